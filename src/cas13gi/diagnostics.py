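"""Screen-quality and guide-interference diagnostics.

Concatenating two spacers behind one promoter can make the position-1
guide's activity depend on the partner sequence in position 2.  The
signature of such cross-guide interference is that the tau profiles of
*different* gene-targeting elements across a shared panel of NTC partners
become correlated (the same partner systematically boosts or dampens every
guide), which never happens when the two guides are expressed from separate
promoters.  This module quantifies that signature:

* replicate and position (orientation) correlations of tau values,
* per-element partner profiles (tau vs each NTC partner),
* a permutation-calibrated interference score: the mean absolute pairwise
  correlation between different elements' partner profiles, compared with a
  null in which each profile's partner labels are shuffled independently.

The interference score is a summary statistic constructed for this package;
its permutation p-value is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import NTC
from .scoring import TauTable, ORIENTATIONS

__all__ = [
    "InterferenceReport",
    "replicate_correlation",
    "position_correlation",
    "partner_profiles",
    "profile_matrix",
    "interference_score",
    "orientation_asymmetry",
]

MIN_SHARED = 3


@dataclass
class InterferenceReport:
    orientation: str
    score: float
    p_value: float
    null_mean: float
    null_q95: float
    n_profiles: int
    n_pairs: int
    skipped_pairs: int
    correlations: pd.DataFrame = field(repr=False, default=None)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < MIN_SHARED:
        return np.nan
    x, y = x[ok], y[ok]
    if x.std() == 0 or y.std() == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def replicate_correlation(table: TauTable, condition: str,
                          method: str = "pearson") -> float:
    """Correlation of construct taus between the first two replicates."""
    sids = table.sample_ids(condition)
    if len(sids) < 2:
        raise ValueError(f"condition {condition!r} has fewer than 2 replicates")
    a = table.tau[sids[0]]
    b = table.tau[sids[1]]
    if len(a) < MIN_SHARED:
        raise ValueError("need at least 3 shared constructs")
    if method == "spearman":
        a, b = a.rank(), b.rank()
    return _pearson(a.to_numpy(), b.to_numpy())


def position_correlation(
    phenotypes: pd.DataFrame, condition: str, method: str = "pearson"
) -> tuple[float, pd.DataFrame]:
    """Pair each element's position-1 phenotype with its position-2 one.

    Returns (r, paired table).  r is NaN (zero-variance flag) when either
    orientation's phenotypes are constant.
    """
    sub = phenotypes[
        (phenotypes["condition"] == condition) & (phenotypes["gene"] != NTC)
    ]
    wide = sub.pivot_table(
        index="element_id", columns="orientation", values="mean_tau_vs_NTC"
    ).dropna()
    if len(wide) < MIN_SHARED:
        raise ValueError("fewer than 3 elements with phenotypes in both positions")
    a, b = wide["pos1"].to_numpy(), wide["pos2"].to_numpy()
    if method == "spearman":
        a = pd.Series(a).rank().to_numpy()
        b = pd.Series(b).rank().to_numpy()
    return _pearson(a, b), wide.reset_index()


def partner_profiles(
    table: TauTable, orientation: str, condition: str
) -> pd.DataFrame:
    """Element x NTC-partner matrix of replicate-mean taus.

    Rows are gene-targeting elements in the given position, columns the NTC
    partner elements in the other position (shared ordering across rows);
    cells without a surviving construct are NaN.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    ann = table.annotations
    own_col, partner_col = ("pos1", "pos2") if orientation == "pos1" else ("pos2", "pos1")
    own_target, partner_target = (
        ("target1", "target2") if orientation == "pos1" else ("target2", "target1")
    )
    mask = (ann[partner_target] == NTC) & (ann[own_target] != NTC)
    sub = ann[mask]
    if sub.empty:
        return pd.DataFrame()
    sids = table.sample_ids(condition)
    per_construct = table.tau.loc[sub.index, sids].mean(axis=1)
    frame = pd.DataFrame(
        dict(element=sub[own_col], partner=sub[partner_col], tau=per_construct)
    )
    mat = frame.pivot_table(index="element", columns="partner", values="tau")
    return mat.sort_index(axis=0).sort_index(axis=1)


def profile_matrix(mat: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between element partner profiles."""
    return mat.T.corr(min_periods=MIN_SHARED)


def _mean_abs_offdiag(x: np.ndarray) -> tuple[float, int, int]:
    """Mean |r| over the strict upper triangle, ignoring NaN pairs."""
    iu = np.triu_indices(x.shape[0], k=1)
    vals = x[iu]
    ok = ~np.isnan(vals)
    return float(np.abs(vals[ok]).mean()) if ok.any() else np.nan, int(ok.sum()), int((~ok).sum())


def _corr_rows(mat: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation matrix for complete data."""
    centred = mat - mat.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=1))
    norms[norms == 0] = np.nan
    unit = centred / norms[:, None]
    return unit @ unit.T


def interference_score(
    profiles: pd.DataFrame,
    permutations: int = 999,
    seed: int = 0,
    orientation: str = "pos1",
) -> InterferenceReport:
    """Permutation-calibrated cross-profile correlation score.

    The observed score is the mean |Pearson r| over all pairs of different
    elements' partner profiles.  The null shuffles each profile's partner
    labels independently (destroying any shared partner structure while
    preserving each profile's values) ``permutations`` times; the empirical
    p-value is ``(1 + #null >= observed) / (permutations + 1)``.
    """
    if profiles.shape[0] < 2 or profiles.shape[1] < MIN_SHARED:
        raise ValueError("need >= 2 profiles over >= 3 shared partners")
    corr = profile_matrix(profiles)
    score, n_pairs, skipped = _mean_abs_offdiag(corr.to_numpy())

    complete = profiles.dropna(axis=1, how="any")
    mat = complete.to_numpy()
    rng = np.random.default_rng(seed)
    e, p = mat.shape
    # permute partner labels independently within each profile, all
    # permutations at once: (B, e, p)
    keys = rng.random((permutations, e, p))
    idx = np.argsort(keys, axis=2)
    perm = np.take_along_axis(np.broadcast_to(mat, (permutations, e, p)), idx, axis=2)
    centred = perm - perm.mean(axis=2, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=2, keepdims=True))
    norms[norms == 0] = np.nan
    unit = centred / norms
    rmats = np.einsum("bep,bfp->bef", unit, unit)
    iu = np.triu_indices(e, k=1)
    null_scores = np.nanmean(np.abs(rmats[:, iu[0], iu[1]]), axis=1)

    p_value = float((1 + np.sum(null_scores >= score)) / (permutations + 1))
    return InterferenceReport(
        orientation=orientation,
        score=score,
        p_value=p_value,
        null_mean=float(np.mean(null_scores)),
        null_q95=float(np.quantile(null_scores, 0.95)),
        n_profiles=e,
        n_pairs=n_pairs,
        skipped_pairs=skipped,
        correlations=corr,
    )


def orientation_asymmetry(
    report_pos1: InterferenceReport, report_pos2: InterferenceReport
) -> dict:
    """Difference in interference score between positions.

    A positive difference with a significant position-1 score flags
    position-1-specific partner interference.
    """
    diff = report_pos1.score - report_pos2.score
    return dict(
        score_pos1=report_pos1.score,
        score_pos2=report_pos2.score,
        difference=float(diff),
        p_pos1=report_pos1.p_value,
        p_pos2=report_pos2.p_value,
        position1_specific=bool(
            diff > 0 and report_pos1.p_value < 0.05 and report_pos2.p_value >= 0.05
        ),
    )
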