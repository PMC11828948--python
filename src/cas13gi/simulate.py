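"""Synthetic dual-perturbation screen generator.

The generator plants a known ground truth — per-gene fitness effects, pairwise
genetic-interaction (GI) terms, per-guide knockdown efficiencies and, for the
concatenated single-promoter strategy, partner-sequence interference — and
produces overdispersed sequencing counts (optionally raw paired FASTQ) with
the replicate and condition structure of a growth-selection screen:

* one baseline (t0) sample taken after library transduction,
* untreated and drug-treated endpoint arms, each with ``replicates``
  independent endpoint samples harvested after ``days`` days of growth.

Growth is exponential in log2 units relative to the non-target controls, so a
construct with fitness ``f`` (log2 units/day) changes its relative abundance
by ``2**(f * days)`` — planted truth therefore maps linearly onto the tau
statistic computed downstream.

Noise model: baseline abundances are LogNormal (library bottleneck), each
sample's reads are multinomial at the sequencing depth, and endpoint samples
receive additional gamma-Poisson (negative-binomial) jitter representing
clonal growth stochasticity; the baseline, being a pre-growth snapshot,
carries sequencing noise only.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BASELINE, TREATED, UNTREATED, ScreenCounts, annotations_from_library
from .library import (
    NTC,
    Construct,
    LibraryDesign,
    build_arrays,
    build_guide_set,
    build_library,
    random_spacer_table,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "build_sim_library",
    "simulate_truth",
    "construct_fitness",
    "simulate_counts",
    "simulate_fastq",
    "simulate_screen",
    "MOTIF_R1",
    "MOTIF_R2",
]

# Diagnostic motifs carried by recombined constructs (single-cassette
# products) in read 1 / read 2.
MOTIF_R1 = "GCTTTAAGGC"
MOTIF_R2 = "CCAACAAGGT"

# Fixed amplicon context flanking the spacer cores, sized to the trimming
# coordinates used downstream: R1 = 74 nt + core + 18 nt, R2 = 59 + core + 33.
R1_CTX5 = ("AGTCCATGAC" * 8)[:74]
R1_CTX3 = ("TTGACGCATA" * 2)[:18]
R2_CTX5 = ("CATGGATCGA" * 6)[:59]
R2_CTX3 = ("GGATCATGCA" * 4)[:33]

_DEFAULT_GENES = ("ABL1", "GAB2", "SOS1", "PTPN1", "NF1", "SPRED2")

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimConfig:
    """Study conditions for one synthetic screen."""

    strategy: str = "U6-g1-U6-g2"
    genes: tuple[str, ...] = _DEFAULT_GENES
    guides_per_gene: int = 27
    ntc_count: int = 30
    arrays_per_gene: int = 9       # array strategy only
    ntc_arrays: int = 10
    replicates: int = 2
    days: float = 19.0
    coverage: float = 1000.0       # reads per construct; depth = coverage * n
    depth: int | None = None       # explicit total reads per sample, overrides
    dispersion: float = 0.05       # NB overdispersion of endpoint counts
    baseline_sigma: float = 0.5    # LogNormal sd of baseline abundances
    efficiency_beta: tuple[float, float] = (5.0, 2.0)
    treated_effect: float = 0.05   # |log2 fitness/day| under drug
    untreated_effect: float = 0.01  # |log2 fitness/day| without drug
    gene_effects: dict | None = None   # (gene, condition) -> log2/day override
    gi_effects: dict | None = None     # (geneA, geneB, condition) -> log2/day
    interference_sd: float = 0.0   # sd of shared per-partner log factors
    error_rate: float = 0.001      # per-base substitution rate in FASTQ
    recombined_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.days <= 0:
            raise ValueError("days must be positive")
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")

    def resolved_depth(self, n_constructs: int) -> int:
        return int(self.depth if self.depth is not None else self.coverage * n_constructs)

    def to_json(self) -> str:
        d = asdict(self)
        d["gene_effects"] = (
            None if self.gene_effects is None
            else {"|".join(k): v for k, v in self.gene_effects.items()}
        )
        d["gi_effects"] = (
            None if self.gi_effects is None
            else {"|".join(k): v for k, v in self.gi_effects.items()}
        )
        return json.dumps(d, indent=2, sort_keys=True)


@dataclass
class SimTruth:
    """Planted ground truth of one simulated screen."""

    strategy: str
    gene_effect: dict          # (gene, condition) -> log2 fitness / day
    gi_true: dict              # (geneA<=geneB, condition) -> log2/day GI term
    guide_efficiency: dict     # element_id -> [0, 1]
    partner_log_interference: dict  # pos2 element_id -> shared log factor
    pair_log_interference: dict     # (pos1, pos2) -> pair-specific log factor
    seed: int

    def gi(self, gene_a: str, gene_b: str, condition: str) -> float:
        if NTC in (gene_a, gene_b):
            return 0.0
        key = (*sorted((gene_a, gene_b)), condition)
        return self.gi_true.get(key, 0.0)

    def interference_factor(self, pos1: str, pos2: str) -> float:
        """Activity modifier of the position-1 element; 1 outside U6-g1-g2."""
        if self.strategy != "U6-g1-g2":
            return 1.0
        z = self.partner_log_interference.get(pos2, 0.0)
        z += self.pair_log_interference.get((pos1, pos2), 0.0)
        return float(np.exp(z))

    def interference_frame(self, library: LibraryDesign) -> pd.DataFrame:
        rows = [
            dict(pos1=c.pos1, pos2=c.pos2,
                 factor=self.interference_factor(c.pos1, c.pos2))
            for c in library.constructs
        ]
        return pd.DataFrame(rows)


def build_sim_library(config: SimConfig) -> LibraryDesign:
    """Design the library implied by the config, with random unique spacers."""
    ss = np.random.SeedSequence([config.seed, 101])
    spacer_seed = int(ss.generate_state(1)[0] % (2**31))
    table = random_spacer_table(
        config.genes, config.guides_per_gene, config.ntc_count,
        seed=spacer_seed, avoid=(MOTIF_R1, revcomp(MOTIF_R2)),
    )
    guides = build_guide_set(config.genes, config.guides_per_gene,
                             config.ntc_count, table)
    if config.strategy == "U6-a1-U6-a2":
        arrays = build_arrays(guides, config.arrays_per_gene,
                              config.ntc_arrays, seed=spacer_seed + 1)
        return build_library(arrays, config.strategy)
    return build_library(guides, config.strategy)


def simulate_truth(config: SimConfig, library: LibraryDesign) -> SimTruth:
    """Draw the planted truth for a library under the configured conditions.

    Unless explicit ``gene_effects`` are given, the first half of the genes
    get negative treated-condition effects (drug-sensitising) and the second
    half positive ones (desensitising), with small same-sign untreated
    effects.  Guide efficiencies are Beta-distributed; an array's efficiency
    is the max over its member guides (arrays knock down more strongly).
    Partner interference exists only for the concatenated strategy: each
    position-2 element carries a shared LogNormal log-activity shift applied
    to any gene-targeting position-1 guide, plus a half-sd pair-specific
    component.
    """
    ss = np.random.SeedSequence([config.seed, 202])
    r_eff, r_intf = [np.random.default_rng(s) for s in ss.spawn(2)]

    gene_effect: dict = {}
    if config.gene_effects is not None:
        gene_effect.update(config.gene_effects)
    else:
        half = len(config.genes) // 2
        for i, g in enumerate(config.genes):
            sign = -1.0 if i < half else 1.0
            gene_effect[(g, TREATED)] = sign * config.treated_effect
            gene_effect[(g, UNTREATED)] = sign * config.untreated_effect

    gi_true: dict = {}
    if config.gi_effects is not None:
        for (ga, gb, cond), v in config.gi_effects.items():
            gi_true[(*sorted((ga, gb)), cond)] = v

    guide_efficiency: dict = {}
    a, b = config.efficiency_beta
    for e in library.elements:
        if e.element_kind == "guide":
            eff = 0.0 if e.is_ntc else float(r_eff.beta(a, b))
            guide_efficiency[e.element_id] = eff
        else:
            members = []
            for mid in e.members:
                if mid not in guide_efficiency:
                    guide_efficiency[mid] = 0.0 if e.is_ntc else float(r_eff.beta(a, b))
                members.append(guide_efficiency[mid])
            guide_efficiency[e.element_id] = max(members)

    partner_log: dict = {}
    pair_log: dict = {}
    if config.strategy == "U6-g1-g2" and config.interference_sd > 0:
        sd = config.interference_sd
        for e in library.elements:
            partner_log[e.element_id] = float(r_intf.normal(0.0, sd))
        for c in library.constructs:
            if library.target_of(c.pos1) != NTC:
                key = (c.pos1, c.pos2)
                if key not in pair_log:
                    pair_log[key] = float(r_intf.normal(0.0, sd / 2.0))

    return SimTruth(
        strategy=config.strategy,
        gene_effect=gene_effect,
        gi_true=gi_true,
        guide_efficiency=guide_efficiency,
        partner_log_interference=partner_log,
        pair_log_interference=pair_log,
        seed=config.seed,
    )


def construct_fitness(construct: Construct, truth: SimTruth,
                      condition: str, library: LibraryDesign) -> float:
    """Per-day log2 fitness of a construct relative to NTC-NTC.

    ``f = eff1*m*effect(g1) + eff2*effect(g2) + eff1*m*eff2*gi(g1, g2)``
    where ``m`` is the position-1 interference factor.  NTC elements
    contribute zero effect.
    """
    t1 = library.target_of(construct.pos1)
    t2 = library.target_of(construct.pos2)
    eff1 = truth.guide_efficiency[construct.pos1]
    eff2 = truth.guide_efficiency[construct.pos2]
    m = truth.interference_factor(construct.pos1, construct.pos2)
    f = 0.0
    if t1 != NTC:
        f += eff1 * m * truth.gene_effect.get((t1, condition), 0.0)
    if t2 != NTC:
        f += eff2 * truth.gene_effect.get((t2, condition), 0.0)
    if t1 != NTC and t2 != NTC:
        f += eff1 * m * eff2 * truth.gi(t1, t2, condition)
    return float(f)


def _fitness_vector(truth: SimTruth, library: LibraryDesign, condition: str) -> np.ndarray:
    return np.array(
        [construct_fitness(c, truth, condition, library) for c in library.constructs]
    )


def _nb_jitter(rng: np.random.Generator, counts: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion <= 0:
        return counts
    out = np.zeros_like(counts)
    pos = counts > 0
    lam = rng.gamma(1.0 / dispersion, counts[pos] * dispersion)
    out[pos] = rng.poisson(lam)
    return out


def simulate_counts(truth: SimTruth, library: LibraryDesign,
                    config: SimConfig) -> ScreenCounts:
    """Draw the construct x sample count matrix for a full screen."""
    n = len(library.constructs)
    depth = config.resolved_depth(n)
    if depth < n:
        import warnings

        warnings.warn(f"depth {depth} below construct count {n}: sparse counts")

    ss = np.random.SeedSequence([config.seed, 303])
    r_base, r_samples = [np.random.default_rng(s) for s in ss.spawn(2)]

    baseline_abundance = r_base.lognormal(0.0, config.baseline_sigma, size=n)

    cols: dict[str, np.ndarray] = {}
    meta: list[dict] = []

    p0 = baseline_abundance / baseline_abundance.sum()
    cols["t0"] = r_samples.multinomial(depth, p0)
    meta.append(dict(sample_id="t0", condition=BASELINE, replicate=0, day=0.0))

    for condition in (UNTREATED, TREATED):
        f = _fitness_vector(truth, library, condition)
        growth = baseline_abundance * np.exp2(f * config.days)
        p = growth / growth.sum()
        for rep in range(1, config.replicates + 1):
            raw = r_samples.multinomial(depth, p)
            cols_name = f"{condition}_r{rep}"
            cols[cols_name] = _nb_jitter(r_samples, raw, config.dispersion)
            meta.append(dict(sample_id=cols_name, condition=condition,
                             replicate=rep, day=config.days))

    index = pd.Index([c.construct_id for c in library.constructs], name="construct_id")
    counts = pd.DataFrame(cols, index=index)
    samples = pd.DataFrame(meta).set_index("sample_id")
    return ScreenCounts(counts=counts, samples=samples,
                        annotations=annotations_from_library(library))


# ---------------------------------------------------------------------------
# FASTQ emission


def _cores(construct: Construct, library: LibraryDesign) -> tuple[str, str]:
    """(position-1 core, position-2 core) as sequenced, before orientation."""
    e1 = library.element(construct.pos1)
    e2 = library.element(construct.pos2)
    core1 = e1.spacer                       # first member spacer for arrays
    core2 = e2.last_spacer if e2.element_kind == "array" else e2.spacer
    return core1, core2


def reference_core(construct: Construct, library: LibraryDesign) -> str:
    """Construct-identifying sequence: pos1 core + pos2 core."""
    core1, core2 = _cores(construct, library)
    return core1 + core2


def _add_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _open_text(path: str | Path, mode: str = "wt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def simulate_fastq(truth: SimTruth, library: LibraryDesign, config: SimConfig,
                   out_r1: str | Path, out_r2: str | Path,
                   n_reads: int | None = None) -> tuple[pd.Series, dict]:
    """Emit a baseline-sample paired FASTQ plus its true construct counts.

    R1 covers the position-1 spacer core inside fixed 74/18-nt context; R2
    reads the bottom strand, covering the reverse complement of the
    position-2 core inside fixed 59/33-nt context.  A ``recombined_fraction``
    of pairs carry the single-cassette recombination motifs and are excluded
    from the returned truth counts.

    Returns ``(truth_counts, report)`` where report tallies total and
    recombined pairs.
    """
    n = len(library.constructs)
    total = int(n_reads if n_reads is not None else config.resolved_depth(n))
    ss = np.random.SeedSequence([config.seed, 404])
    r_base, r_pick, r_err = [np.random.default_rng(s) for s in ss.spawn(3)]

    abundance = r_base.lognormal(0.0, config.baseline_sigma, size=n)
    p = abundance / abundance.sum()
    picks = r_pick.choice(n, size=total, p=p)
    recomb = r_pick.random(total) < config.recombined_fraction

    index = pd.Index([c.construct_id for c in library.constructs], name="construct_id")

    with _open_text(out_r1) as f1, _open_text(out_r2) as f2:
        for i in range(total):
            c = library.constructs[picks[i]]
            core1, core2 = _cores(c, library)
            r1 = R1_CTX5 + core1 + R1_CTX3
            r2 = R2_CTX5 + revcomp(core2) + R2_CTX3
            if recomb[i]:
                r1 = MOTIF_R1 + r1[len(MOTIF_R1):]
                r2 = MOTIF_R2 + r2[len(MOTIF_R2):]
            r1 = _add_errors(r_err, r1, config.error_rate)
            r2 = _add_errors(r_err, r2, config.error_rate)
            name = f"@sim_{i} {c.construct_id}"
            f1.write(f"{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
            f2.write(f"{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")

    kept = np.bincount(picks[~recomb], minlength=n)
    truth_counts = pd.Series(kept, index=index, name="reads")

    report = dict(total=total, recombined=int(recomb.sum()))
    return truth_counts, report


def simulate_screen(config: SimConfig) -> tuple[LibraryDesign, SimTruth, ScreenCounts]:
    """Convenience: design library, draw truth, draw counts."""
    library = build_sim_library(config)
    truth = simulate_truth(config, library)
    counts = simulate_counts(truth, library, config)
    return library, truth, counts
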