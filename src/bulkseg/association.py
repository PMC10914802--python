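"""Marker-trait association in the variety panel.

The panel is split at the median of its DRYM ranking into equal tolerant
and sensitive halves.  Each panel SNP is tested two ways: Fisher's exact
test on the 2x2 table of alt-allele carriers versus group (the primary
test, significant at alpha = 0.05 uncorrected), and a Kruskal-Wallis test
of the varieties' DRYM values across genotype classes with the effect
size eta^2 = (H - k + 1) / (n - k).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def split_panel(ranked_varieties) -> tuple[list[str], list[str]]:
    """Top half of a most-tolerant-first ranking -> tolerant group, rest ->
    sensitive; with odd n the middle variety goes to the sensitive group."""
    ranked = list(ranked_varieties)
    if len(ranked) < 4:
        raise ValueError("need at least 4 ranked varieties to split")
    half = len(ranked) // 2
    return ranked[:half], ranked[half:]


def fisher_association(
    panel: pd.DataFrame,
    tolerant: list[str],
    sensitive: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher's exact test per SNP on carriers x group.

    ``panel`` is long format with variety / chrom / pos / alt /
    allele_state in {ref, alt, missing}; missing calls are dropped per
    SNP.  Monomorphic SNPs get p = 1.  BH q-values are attached
    informationally; significance is judged on the raw p at ``alpha``.
    """
    tol = set(tolerant)
    sen = set(sensitive)
    rows = []
    for key, grp in panel.groupby(["chrom", "pos", "alt"], sort=True):
        grp = grp[grp["allele_state"] != "missing"]
        in_tol = grp["variety"].isin(tol)
        in_sen = grp["variety"].isin(sen)
        carrier = grp["allele_state"] == "alt"
        a = int((carrier & in_tol).sum())
        b = int((~carrier & in_tol).sum())
        c = int((carrier & in_sen).sum())
        d = int((~carrier & in_sen).sum())
        if a + b == 0 or c + d == 0:
            continue  # no non-missing calls in one group
        if a + c == 0 or b + d == 0:
            p = 1.0  # monomorphic across the panel
        else:
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        rows.append(
            {
                "chrom": key[0],
                "pos": key[1],
                "alt": key[2],
                "carriers_tol": a,
                "noncarriers_tol": b,
                "carriers_sen": c,
                "noncarriers_sen": d,
                "fisher_p": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fisher_q"] = multipletests(out["fisher_p"], method="fdr_bh")[1]
        out["significant"] = out["fisher_p"] < alpha
    return out


def kruskal_wallis_eta2(values, classes) -> tuple[float, float, float]:
    """Kruskal-Wallis H (tie-corrected), chi-square p on k - 1 df, and the
    eta-squared effect size (H - k + 1) / (n - k).

    ``values`` are per-variety DRYM values, ``classes`` the genotype class
    of each variety at one SNP.  All-tied values give H = 0 and a
    (possibly negative) eta^2 per the formula.
    """
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    groups = [values[classes == c] for c in pd.unique(classes)]
    groups = [g for g in groups if g.size > 0]
    k = len(groups)
    n = values.size
    if k < 2:
        raise ValueError("need at least two genotype classes")
    if all(np.all(g == groups[0][0]) for g in groups):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    eta2 = (h - k + 1) / (n - k)
    return float(h), float(p), float(eta2)


def kw_association(
    panel: pd.DataFrame, drym_by_variety: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Kruskal-Wallis + eta^2 per panel SNP, classes = allele_state."""
    rows = []
    for key, grp in panel.groupby(["chrom", "pos", "alt"], sort=True):
        grp = grp[grp["allele_state"] != "missing"]
        vals = drym_by_variety.reindex(grp["variety"]).to_numpy()
        ok = ~np.isnan(vals)
        classes = grp["allele_state"].to_numpy()[ok]
        vals = vals[ok]
        if pd.unique(classes).size < 2:
            continue
        h, p, eta2 = kruskal_wallis_eta2(vals, classes)
        rows.append(
            {
                "chrom": key[0],
                "pos": key[1],
                "alt": key[2],
                "kw_h": h,
                "kw_p": p,
                "eta_squared": eta2,
                "significant": p < alpha,
            }
        )
    return pd.DataFrame(rows)
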