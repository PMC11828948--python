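"""Fitness (tau) and genetic-interaction (GI) scoring.

The statistic chain, applied independently per condition arm:

1. drop constructs whose mean baseline count falls below a fraction
   (default 10%) of the grand mean baseline count;
2. add a pseudocount and normalise each sample to mean 1, giving relative
   frequencies;
3. per endpoint sample, ``tau_x = log2[(N_t^x / N_t0^x) / (N_t^NTC / N_t0^NTC)]``
   where the NTC aggregate is the mean frequency over NTC-NTC constructs —
   the log2 fitness of construct x relative to the non-target controls;
4. centre every sample's taus on its NTC-NTC mean (which makes step 3's
   choice of NTC aggregate provably irrelevant: any per-sample constant
   cancels);
5. the single-perturbation phenotype of an element in an orientation is its
   mean centred tau over all NTC-partner constructs and replicates;
6. elements whose phenotype is weaker than their gene's mean phenotype in
   both orientations are removed (weak-phenotype filter);
7. the guide-level GI of a double construct is
   ``GI = tau_double - (phi_pos1 + phi_pos2)`` — the deviation of the double
   phenotype from the additive expectation; positive = buffering,
   negative = synergistic.  Same-gene pairs and gene-with-NTC "single gene
   controls" are scored by the same formula as internal control families;
8. GI values are mean-summarised per (gene pair, orientation) and tested
   with a one-sample empirical-Bayes moderated t-test followed by
   Benjamini-Hochberg correction within each record family;
9. a gene pair is a reproducible hit when |GI| and FDR pass their thresholds
   in both orientations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .containers import BASELINE, ScreenCounts
from .library import NTC

__all__ = [
    "TauTable",
    "ScoreResult",
    "filter_low_counts",
    "add_pseudocount",
    "normalize_counts",
    "compute_tau",
    "center_tau",
    "guide_phenotypes",
    "weak_phenotype_filter",
    "compute_gi",
    "fit_variance_prior",
    "summarize_and_test",
    "bh_adjust",
    "call_hits",
    "score_screen",
]

GI_THRESHOLD = 0.2
FDR_THRESHOLD = 0.5
ORIENTATIONS = ("pos1", "pos2")


@dataclass
class TauTable:
    """Centred or raw log2 relative-fitness values.

    ``tau`` is indexed by construct_id with one column per endpoint sample;
    ``samples`` carries (condition, replicate) per column; ``annotations``
    mirrors the count matrix annotations for surviving constructs.
    """

    tau: pd.DataFrame
    samples: pd.DataFrame
    annotations: pd.DataFrame
    centered: bool = False
    params: dict = field(default_factory=dict)

    def conditions(self) -> list[str]:
        return sorted(self.samples["condition"].unique())

    def sample_ids(self, condition: str) -> list[str]:
        return list(self.samples.index[self.samples["condition"] == condition])


# ---------------------------------------------------------------------------
# Count-level preprocessing


def filter_low_counts(
    screen: ScreenCounts, fraction: float = 0.10
) -> tuple[ScreenCounts, list[str]]:
    """Remove constructs under-represented at baseline.

    A construct is dropped when its mean baseline count is below ``fraction``
    times the grand mean of those per-construct baseline means.
    """
    base = screen.counts[screen.baseline_samples].mean(axis=1)
    cutoff = fraction * base.mean()
    removed = list(base.index[base < cutoff])
    kept = base.index[base >= cutoff]
    if len(kept) == 0:
        raise ValueError("low-count filter removed every construct")
    return screen.subset(kept), removed


def add_pseudocount(counts: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return counts.astype(float) + pseudocount


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample by its own mean; column means become exactly 1."""
    means = counts.mean(axis=0)
    if (means <= 0).any():
        raise ValueError("cannot normalise a sample with non-positive mean")
    return counts / means


# ---------------------------------------------------------------------------
# tau


def compute_tau(
    freq: pd.DataFrame,
    screen: ScreenCounts,
    ntc_aggregate: str = "mean",
) -> TauTable:
    """Log2 fitness of each construct relative to the NTC-NTC set (uncentred).

    One tau per construct per endpoint sample (condition x replicate), using
    the screen's single baseline as t0.
    """
    ann = screen.annotations
    ntc_ids = ann.index[ann["pair_class"] == "NTC-NTC"]
    if len(ntc_ids) == 0:
        raise ValueError("no NTC-NTC constructs available for normalisation")
    agg = {"mean": np.mean, "median": np.median}[ntc_aggregate]

    t0 = screen.baseline_samples[0]
    endpoints = screen.samples[screen.samples["condition"] != BASELINE]
    f0 = freq[t0]
    ntc0 = agg(f0.loc[ntc_ids].to_numpy())
    cols = {}
    for sid in endpoints.index:
        ft = freq[sid]
        ntct = agg(ft.loc[ntc_ids].to_numpy())
        cols[sid] = np.log2((ft / f0) / (ntct / ntc0))
    tau = pd.DataFrame(cols, index=freq.index)
    return TauTable(
        tau=tau,
        samples=endpoints[["condition", "replicate", "day"]].copy(),
        annotations=ann.copy(),
        centered=False,
        params=dict(ntc_aggregate=ntc_aggregate),
    )


def center_tau(table: TauTable) -> TauTable:
    """Subtract each sample's NTC-NTC mean tau; their mean becomes 0."""
    ann = table.annotations
    ntc_ids = ann.index[ann["pair_class"] == "NTC-NTC"]
    if len(ntc_ids) == 0:
        raise ValueError("no surviving NTC-NTC constructs to centre on")
    offsets = table.tau.loc[ntc_ids].mean(axis=0)
    return TauTable(
        tau=table.tau - offsets,
        samples=table.samples,
        annotations=ann,
        centered=True,
        params=dict(table.params),
    )


# ---------------------------------------------------------------------------
# phenotypes and the weak-phenotype filter


def guide_phenotypes(table: TauTable, include_ntc: bool = True) -> pd.DataFrame:
    """Single-perturbation phenotype of every element per orientation.

    For each element and condition, ``mean_tau_vs_NTC`` is the mean centred
    tau over all constructs pairing it with an NTC partner, across that
    condition's replicates.  Orientation ``pos1`` means the element occupies
    position 1.  NTC elements (profiled against NTC-NTC constructs) are
    included for the single-gene-control family.
    """
    if not table.centered:
        raise ValueError("phenotypes require centred taus")
    ann = table.annotations
    rows = []
    for condition in table.conditions():
        sids = table.sample_ids(condition)
        per_construct = table.tau[sids].mean(axis=1)
        for orientation in ORIENTATIONS:
            own_col = "pos1" if orientation == "pos1" else "pos2"
            partner_target = "target2" if orientation == "pos1" else "target1"
            own_target = "target1" if orientation == "pos1" else "target2"
            mask = ann[partner_target] == NTC
            if not include_ntc:
                mask &= ann[own_target] != NTC
            sub = ann[mask]
            grouped = per_construct.loc[sub.index].groupby(sub[own_col])
            for element_id, values in grouped:
                rows.append(
                    dict(
                        element_id=element_id,
                        gene=sub.loc[sub[own_col] == element_id, own_target].iloc[0],
                        orientation=orientation,
                        condition=condition,
                        mean_tau_vs_NTC=float(values.mean()),
                        n_partners=int(values.size),
                    )
                )
    return pd.DataFrame(rows)


def weak_phenotype_filter(
    phenotypes: pd.DataFrame, mode: str = "signed"
) -> tuple[pd.DataFrame, dict]:
    """Flag elements with weak single-perturbation phenotypes.

    Per gene and orientation the cutoff is the mean of its elements'
    phenotypes.  In ``signed`` mode an element passes when its phenotype is
    at least as extreme as the cutoff in the cutoff's own sign direction; in
    ``magnitude`` mode when |phenotype| >= |cutoff|.  Ties pass.  An element
    is removed only when it fails in BOTH orientations (per condition).

    Returns the phenotype table with a ``passes_filter`` column and a map
    ``condition -> set of removed element ids``.  NTC elements always pass.
    """
    if mode not in ("signed", "magnitude"):
        raise ValueError(f"unknown filter mode {mode!r}")
    ph = phenotypes.copy()
    ph["passes_filter"] = True
    for (gene, orientation, condition), idx in ph.groupby(
        ["gene", "orientation", "condition"]
    ).groups.items():
        if gene == NTC:
            continue
        vals = ph.loc[idx, "mean_tau_vs_NTC"]
        cutoff = vals.mean()
        if mode == "magnitude":
            ok = vals.abs() >= abs(cutoff) - 1e-12
        elif cutoff < 0:
            ok = vals <= cutoff + 1e-12
        elif cutoff > 0:
            ok = vals >= cutoff - 1e-12
        else:
            ok = pd.Series(True, index=vals.index)
        ph.loc[idx, "passes_filter"] = ok

    removed: dict = {}
    for condition, sub in ph.groupby("condition"):
        gene_sub = sub[sub["gene"] != NTC]
        fails = gene_sub.groupby("element_id")["passes_filter"].sum() == 0
        removed[condition] = set(fails.index[fails])
    return ph, removed


# ---------------------------------------------------------------------------
# GI


def _phi_lookup(phenotypes: pd.DataFrame) -> dict:
    return {
        (r.element_id, r.orientation, r.condition): r.mean_tau_vs_NTC
        for r in phenotypes.itertuples()
    }


def compute_gi(
    table: TauTable,
    phenotypes: pd.DataFrame,
    removed: dict | None = None,
) -> pd.DataFrame:
    """Guide-level GI values for all three record families.

    One row per (construct, condition, replicate):
    ``gi = tau_double - (phi_pos1 + phi_pos2)``.  For single-gene controls
    the NTC side's expectation is the mean phenotype of all NTC elements in
    that orientation.  Constructs whose gene-targeting element was removed by
    the weak-phenotype filter are skipped; a ``skipped`` attribute on the
    returned frame tallies them.
    """
    if not table.centered:
        raise ValueError("GI requires centred taus")
    removed = removed or {}
    phi = _phi_lookup(phenotypes)
    ann = table.annotations

    ntc_phi: dict = {}
    ntc_rows = phenotypes[phenotypes["gene"] == NTC]
    for (orientation, condition), sub in ntc_rows.groupby(["orientation", "condition"]):
        ntc_phi[(orientation, condition)] = float(sub["mean_tau_vs_NTC"].mean())

    rows = []
    skipped = 0
    classes = {"gene-gene", "same-gene", "gene-NTC", "NTC-gene"}
    sub_ann = ann[ann["pair_class"].isin(classes)]
    for condition in table.conditions():
        sids = table.sample_ids(condition)
        reps = table.samples.loc[sids, "replicate"]
        gone = removed.get(condition, set())
        for c in sub_ann.itertuples():
            t1, t2 = c.target1, c.target2
            pc = c.pair_class
            if pc == "gene-gene" or pc == "same-gene":
                if c.pos1 in gone or c.pos2 in gone:
                    skipped += 1
                    continue
                p1 = phi.get((c.pos1, "pos1", condition))
                p2 = phi.get((c.pos2, "pos2", condition))
                if p1 is None or p2 is None:
                    skipped += 1
                    continue
                if pc == "same-gene":
                    gene_a = gene_b = t1
                    orientation = "both"
                else:
                    gene_a, gene_b = sorted((t1, t2))
                    orientation = "pos1" if t1 == gene_a else "pos2"
                record_class = pc
            elif pc == "gene-NTC":
                if c.pos1 in gone:
                    skipped += 1
                    continue
                p1 = phi.get((c.pos1, "pos1", condition))
                p2 = ntc_phi.get(("pos2", condition), 0.0)
                if p1 is None:
                    skipped += 1
                    continue
                gene_a, gene_b = t1, NTC
                orientation = "pos1"
                record_class = "single-gene-control"
            else:  # NTC-gene
                if c.pos2 in gone:
                    skipped += 1
                    continue
                p1 = ntc_phi.get(("pos1", condition), 0.0)
                p2 = phi.get((c.pos2, "pos2", condition))
                if p2 is None:
                    skipped += 1
                    continue
                gene_a, gene_b = t2, NTC
                orientation = "pos2"
                record_class = "single-gene-control"

            expected = p1 + p2
            for sid in sids:
                rows.append(
                    dict(
                        construct_id=c.Index,
                        gene_a=gene_a,
                        gene_b=gene_b,
                        orientation=orientation,
                        condition=condition,
                        replicate=int(reps[sid]),
                        gi=float(table.tau.at[c.Index, sid] - expected),
                        record_class=record_class,
                    )
                )
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


# ---------------------------------------------------------------------------
# moderated testing


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F variance prior (d0, s0^2).

    Models sample variances as ``s^2 ~ s0^2 * F(df, d0)`` and matches the
    mean and variance of ``log s^2`` using digamma/trigamma identities.
    ``d0 = inf`` (with ``s0^2`` the common variance) when the observed
    log-variances are no more dispersed than chi-square sampling alone
    explains.
    """
    s2 = np.asarray(s2, float)
    df = np.broadcast_to(np.asarray(df, float), s2.shape)
    ok = (s2 > 0) & (df > 0)
    s2, df = s2[ok], df[ok]
    if s2.size == 0:
        raise ValueError("no positive variances to moderate")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    if s2.size < 2:
        return np.inf, float(s2.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0).mean())
    if evar <= 0:
        # log-variances no more spread than sampling noise: infinite prior
        # df, prior variance = pooled variance
        return np.inf, float(s2.mean())
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_one_sample_test(
    means: np.ndarray, s2: np.ndarray, n: np.ndarray,
    d0: float, s0_2: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Moderated t, two-sided p and posterior variances for group means."""
    means = np.asarray(means, float)
    s2 = np.asarray(s2, float)
    n = np.asarray(n, float)
    d = n - 1.0
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.full_like(s2, np.inf)
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d
    t = means / np.sqrt(s2_post / n)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return t, p, s2_post


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR: q_(i) = min_{j>=i} m*p_(j)/j, <= 1."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


def summarize_and_test(guide_gi: pd.DataFrame) -> pd.DataFrame:
    """Mean-summarise guide-level GI per (gene pair, orientation, condition)
    and test each mean against zero with the moderated t-test.

    The variance prior is fitted across all groups of a condition; BH
    adjustment runs within each (condition, record family) so the control
    families do not dilute the gene-gene family.
    """
    if guide_gi.empty:
        return pd.DataFrame(
            columns=["gene_a", "gene_b", "orientation", "condition",
                     "record_class", "n", "gene_gi", "t_moderated",
                     "p_value", "fdr"]
        )
    grouped = guide_gi.groupby(
        ["condition", "record_class", "gene_a", "gene_b", "orientation"]
    )["gi"]
    summary = grouped.agg(n="size", gene_gi="mean", s2="var").reset_index()

    summary["t_moderated"] = np.nan
    summary["p_value"] = np.nan
    for condition, idx in summary.groupby("condition").groups.items():
        sub = summary.loc[idx]
        testable = sub[sub["n"] >= 2]
        if testable.empty:
            continue
        d0, s0_2 = fit_variance_prior(
            testable["s2"].to_numpy(), testable["n"].to_numpy() - 1.0
        )
        t, p, _ = moderated_one_sample_test(
            testable["gene_gi"].to_numpy(), testable["s2"].to_numpy(),
            testable["n"].to_numpy(), d0, s0_2,
        )
        summary.loc[testable.index, "t_moderated"] = t
        summary.loc[testable.index, "p_value"] = p

    summary["fdr"] = np.nan
    for (_, _), idx in summary.groupby(["condition", "record_class"]).groups.items():
        summary.loc[idx, "fdr"] = bh_adjust(summary.loc[idx, "p_value"].to_numpy())
    return summary.drop(columns=["s2"])


def call_hits(
    records: pd.DataFrame,
    gi_threshold: float = GI_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag per-record hits and build the reproducible-hit edge list.

    A record is a hit when |gene_gi| > gi_threshold and fdr < fdr_threshold.
    A gene-gene pair enters the network (per condition) only when it is a hit
    in BOTH orientations; the edge weight is the mean GI over orientations,
    its sign buffering (+) or synergistic (-).
    """
    rec = records.copy()
    rec["hit"] = (
        (rec["gene_gi"].abs() > gi_threshold) & (rec["fdr"] < fdr_threshold)
    ).fillna(False)

    edges = []
    gg = rec[rec["record_class"] == "gene-gene"]
    for (condition, ga, gb), sub in gg.groupby(["condition", "gene_a", "gene_b"]):
        if set(sub["orientation"]) != set(ORIENTATIONS):
            continue
        if sub["hit"].all():
            edges.append(
                dict(
                    condition=condition, gene_a=ga, gene_b=gb,
                    gi=float(sub["gene_gi"].mean()),
                    sign="buffering" if sub["gene_gi"].mean() > 0 else "synergistic",
                )
            )
    return rec, pd.DataFrame(edges, columns=["condition", "gene_a", "gene_b", "gi", "sign"])


# ---------------------------------------------------------------------------
# end-to-end convenience


@dataclass
class ScoreResult:
    tau: TauTable
    phenotypes: pd.DataFrame
    removed_low_count: list[str]
    removed_weak: dict
    guide_gi: pd.DataFrame
    records: pd.DataFrame
    edges: pd.DataFrame


def score_screen(
    screen: ScreenCounts,
    pseudocount: float = 1.0,
    low_count_fraction: float = 0.10,
    gi_threshold: float = GI_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
    filter_mode: str = "signed",
    ntc_aggregate: str = "mean",
) -> ScoreResult:
    """Run the full scoring chain on a count matrix."""
    filtered, removed_ids = filter_low_counts(screen, low_count_fraction)
    freq = normalize_counts(add_pseudocount(filtered.counts, pseudocount))
    table = center_tau(compute_tau(freq, filtered, ntc_aggregate))
    phenotypes = guide_phenotypes(table)
    phenotypes, removed_weak = weak_phenotype_filter(phenotypes, filter_mode)
    guide_gi = compute_gi(table, phenotypes, removed_weak)
    records = summarize_and_test(guide_gi)
    records, edges = call_hits(records, gi_threshold, fdr_threshold)
    return ScoreResult(
        tau=table,
        phenotypes=phenotypes,
        removed_low_count=removed_ids,
        removed_weak=removed_weak,
        guide_gi=guide_gi,
        records=records,
        edges=edges,
    )
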