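"""Gene-family variability enrichment with UTR-bias control.

UTR probes diverge faster between strains than CDS probes, so a family
rich in UTR probes looks "variable" for trivial reasons. Every family
test is therefore run against two backgrounds: the proportion of variable
probes among all probes, and among UTR probes only. A family that is
significant against both is variable beyond what its UTR content
explains.

The family test is an exact one-sided binomial: with k variable probes
out of n family probes and background proportion p0, the p-value is
P(X >= k | n, p0). Background proportions exclude the family's own probes
by default.

A generic category test (hypergeometric per label, Benjamini-Hochberg
FDR) covers annotation-driven enrichment of arbitrary label maps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .arrayio import UTR, ArrayDesign
from .normalize import RatioTrack

__all__ = [
    "UtrBiasProfile",
    "EnrichmentResult",
    "utr_bias_profile",
    "binomial_enrichment",
    "family_enrichment",
    "category_enrichment_fdr",
]


@dataclass
class UtrBiasProfile:
    n_probes: int
    n_utr: int
    n_variable: int
    n_variable_utr: int
    biased: bool

    @property
    def overall_utr_share(self) -> float:
        return self.n_utr / self.n_probes if self.n_probes else float("nan")

    @property
    def variable_utr_share(self) -> float:
        return self.n_variable_utr / self.n_variable if self.n_variable else float("nan")


def utr_bias_profile(track: RatioTrack, design: ArrayDesign, threshold: float = 1.0) -> UtrBiasProfile:
    """UTR share overall vs among variable probes (|M| > threshold)."""
    t = design.table.merge(track.table[["probe_id", "M"]], on="probe_id", how="inner")
    is_utr = (t["region"] == UTR).to_numpy()
    variable = (t["M"].abs() > threshold).to_numpy()
    n, n_utr = len(t), int(is_utr.sum())
    n_var, n_var_utr = int(variable.sum()), int((variable & is_utr).sum())
    biased = n_var > 0 and (n_var_utr / n_var) > (n_utr / n)
    return UtrBiasProfile(n_probes=n, n_utr=n_utr, n_variable=n_var, n_variable_utr=n_var_utr, biased=biased)


def binomial_enrichment(k: int, n: int, p0: float, direction: str = "over") -> float:
    """Exact binomial tail p-value.

    ``over``: P(X >= k); ``under``: P(X <= k); ``two-sided``: exact
    two-sided test.
    """
    if not 0 <= k <= n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"background proportion must be in (0,1), got {p0}")
    alt = {"over": "greater", "under": "less", "two-sided": "two-sided"}[direction]
    return float(stats.binomtest(k, n, p0, alternative=alt).pvalue)


@dataclass
class EnrichmentResult:
    strain: str
    family: str
    k: int
    n: int
    p_all: float
    p_utr: float
    pvalue_vs_all: float
    pvalue_vs_utr: float
    direction: str = "over"


def family_enrichment(
    track: RatioTrack,
    design: ArrayDesign,
    family: str,
    threshold: float = 1.0,
    direction: str = "over",
    exclude_family_from_background: bool = True,
) -> EnrichmentResult:
    """Test a family's probes for excess variability against both backgrounds.

    k = variable probes in the family, n = family probes on the whole
    array; backgrounds are the variable-probe proportion among all probes
    and among UTR probes (family probes excluded by default).
    """
    t = design.table.merge(track.table[["probe_id", "M"]], on="probe_id", how="inner")
    in_fam = t["families"].str.split(",").apply(lambda fs: family in fs).to_numpy()
    if not in_fam.any():
        raise ValueError(f"family {family!r} has no probes on the array")
    variable = (t["M"].abs() > threshold).to_numpy()
    is_utr = (t["region"] == UTR).to_numpy()

    bg = ~in_fam if exclude_family_from_background else np.ones(len(t), bool)
    p_all = variable[bg].mean()
    p_utr = variable[bg & is_utr].mean()
    k = int(variable[in_fam].sum())
    n = int(in_fam.sum())
    return EnrichmentResult(
        strain=track.strain,
        family=family,
        k=k,
        n=n,
        p_all=float(p_all),
        p_utr=float(p_utr),
        pvalue_vs_all=binomial_enrichment(k, n, p_all, direction),
        pvalue_vs_utr=binomial_enrichment(k, n, p_utr, direction),
        direction=direction,
    )


def category_enrichment_fdr(
    category_map: dict[str, set[str] | list[str]],
    target: set[str],
    universe: set[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation per label with BH-FDR control.

    ``category_map`` maps seq_id -> labels. Returns one row per label with
    counts, raw p-value, BH-adjusted q-value and a ``significant`` flag at
    the requested FDR.
    """
    universe = set(universe)
    target = set(target)
    if not universe:
        raise ValueError("universe is empty")
    if not target <= universe:
        raise ValueError("target set must be a subset of the universe")
    label_members: dict[str, set[str]] = {}
    for seq, labels in category_map.items():
        if seq not in universe:
            continue
        for lab in labels:
            label_members.setdefault(lab, set()).add(seq)
    rows = []
    n_univ, n_target = len(universe), len(target)
    for lab, members in sorted(label_members.items()):
        n_lab = len(members)
        k = len(members & target)
        # P(X >= k) drawing n_target from universe with n_lab successes
        p = float(stats.hypergeom.sf(k - 1, n_univ, n_lab, n_target))
        rows.append({"label": lab, "k": k, "n_label": n_lab, "n_target": n_target, "n_universe": n_univ, "pvalue": p})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(qvalue=[], significant=[])
    rej, qvals, _, _ = multipletests(df["pvalue"], alpha=fdr, method="fdr_bh")
    df["qvalue"] = qvals
    df["significant"] = rej
    return df
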