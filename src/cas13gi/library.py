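"""Combinatorial Cas13d dual-guide library design.

A library is built from *elements* — either single 23-nt spacers (guides) or
3-guide same-gene arrays — placed into two expression positions under one of
three cloning strategies:

``U6-g1-g2``
    Two guides concatenated behind a single mouse U6 promoter.  Cloning only
    yields combinations in which at least one position carries a non-target
    control (NTC): every element is paired with every NTC in each position.
``U6-g1-U6-g2``
    Each guide expressed from its own promoter (mU6 / hU6); the library is the
    full ordered cross of all elements.
``U6-a1-U6-a2``
    Like the dual-promoter strategy but each element is a 3-guide same-gene
    array, shrinking the cross 9-fold at equal gene coverage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DR36",
    "NTC",
    "STRATEGIES",
    "GuideElement",
    "GuideArray",
    "Construct",
    "LibraryDesign",
    "build_guide_set",
    "build_arrays",
    "build_library",
    "render_oligo",
    "random_spacer_table",
]

NTC = "NTC"
SPACER_LEN = 23
STRATEGIES = ("U6-g1-g2", "U6-g1-U6-g2", "U6-a1-U6-a2")

#: RfxCas13d 36-nt direct repeat used to separate spacers inside an array.
DR36 = "CAAGTAAACCCCTACCAACTGGTCGGGGTTTGAAAC"

# Synthesis templates: prefix/suffix flanks around the variable insert.
# Dual-promoter strategies share one per-element template; the concatenated
# strategy uses distinct position-1 / position-2 templates with the direct
# repeat built into the flanks.
DUAL_PREFIX = "AGTATGCACAGTTGATCCGTCTCAAAAC"
DUAL_SUFFIX = "CAAGAGAGACGGTTCACTGTAGCA"
CONCAT_P1_PREFIX = "AGTATGCACAGTTGATCCGTCTCATTGG"
CONCAT_P1_SUFFIX = "CAAGTAAACCCCTACCAACTAGAGACGGTTCACTGTAGCA"
CONCAT_P2_PREFIX = "AGTATGCACAGTTGATCCGTCTCAAACTGGTCGGGGTTTGAAAC"
CONCAT_P2_SUFFIX = "GCTTTAAAGAGACGGTTCACTGTAGCA"

_ALPHABET = set("ACGT")


class LibraryError(ValueError):
    """Invalid library configuration or input table."""


def _check_spacer(spacer: str, owner: str) -> str:
    spacer = spacer.upper()
    if len(spacer) != SPACER_LEN:
        raise LibraryError(
            f"spacer for {owner!r} has length {len(spacer)}, expected {SPACER_LEN}"
        )
    if not set(spacer) <= _ALPHABET:
        raise LibraryError(f"spacer for {owner!r} contains non-ACGT characters")
    return spacer


@dataclass(frozen=True)
class GuideElement:
    """A single 23-nt spacer with its target identity and selection metadata."""

    element_id: str
    target: str              # gene symbol or "NTC"
    spacer: str
    group: int               # selection-criterion group, 1-3
    rank: int                # rank within group, 1-based
    element_kind: str = "guide"

    def __post_init__(self) -> None:
        if self.element_kind == "guide":
            object.__setattr__(self, "spacer", _check_spacer(self.spacer, self.element_id))

    @property
    def is_ntc(self) -> bool:
        return self.target == NTC


@dataclass(frozen=True)
class GuideArray:
    """Three guides against one target concatenated with direct repeats."""

    element_id: str
    target: str
    members: tuple[str, str, str]       # member element ids, ordered
    spacers: tuple[str, str, str]       # member spacers, same order
    element_kind: str = "array"

    @property
    def is_ntc(self) -> bool:
        return self.target == NTC

    def rendered_insert(self, dr36: str = DR36) -> str:
        return dr36.join(self.spacers)

    # The counting unit reads the first spacer when the array sits in
    # position 1 and the last spacer when it sits in position 2.
    @property
    def spacer(self) -> str:
        return self.spacers[0]

    @property
    def last_spacer(self) -> str:
        return self.spacers[2]


@dataclass(frozen=True)
class Construct:
    """An ordered (position-1, position-2) pairing of two elements."""

    construct_id: str
    pos1: str
    pos2: str
    pair_class: str  # gene-gene | gene-NTC | NTC-gene | NTC-NTC | same-gene


def _pair_class(t1: str, t2: str) -> str:
    if t1 == NTC and t2 == NTC:
        return "NTC-NTC"
    if t1 == NTC:
        return "NTC-gene"
    if t2 == NTC:
        return "gene-NTC"
    if t1 == t2:
        return "same-gene"
    return "gene-gene"


@dataclass
class LibraryDesign:
    """A fully enumerated dual-perturbation library."""

    strategy: str
    elements: list
    constructs: list[Construct]
    dr36: str = DR36

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise LibraryError(f"unknown strategy {self.strategy!r}")
        if len(self.dr36) != 36:
            raise LibraryError(f"DR36 must be 36 nt, got {len(self.dr36)}")
        self._by_id = {e.element_id: e for e in self.elements}
        for c in self.constructs:
            if c.pos1 not in self._by_id or c.pos2 not in self._by_id:
                raise LibraryError(f"construct {c.construct_id} references unknown element")

    def element(self, element_id: str):
        return self._by_id[element_id]

    def target_of(self, element_id: str) -> str:
        return self._by_id[element_id].target

    @property
    def ntc_ids(self) -> list[str]:
        return [e.element_id for e in self.elements if e.is_ntc]

    @property
    def gene_element_ids(self) -> list[str]:
        return [e.element_id for e in self.elements if not e.is_ntc]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.elements:
            if not e.is_ntc:
                seen.setdefault(e.target, None)
        return list(seen)

    def elements_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.elements:
            rows.append(
                dict(
                    element_id=e.element_id,
                    target=e.target,
                    spacer=e.spacer,
                    group=getattr(e, "group", 0),
                    rank=getattr(e, "rank", 0),
                    element_kind=e.element_kind,
                    members=";".join(e.members) if e.element_kind == "array" else "",
                )
            )
        return pd.DataFrame(rows)

    def constructs_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            dict(
                construct_id=[c.construct_id for c in self.constructs],
                pos1=[c.pos1 for c in self.constructs],
                pos2=[c.pos2 for c in self.constructs],
                pair_class=[c.pair_class for c in self.constructs],
            )
        )
        df["target1"] = df["pos1"].map(self.target_of)
        df["target2"] = df["pos2"].map(self.target_of)
        return df


def build_guide_set(
    genes: Sequence[str],
    guides_per_gene: int,
    ntc_count: int,
    spacer_source: Mapping[str, Sequence[str]],
) -> list[GuideElement]:
    """Select guides for each gene plus a non-target control set.

    ``spacer_source`` maps each gene symbol (and the key ``"NTC"``) to an
    ordered list of candidate 23-nt spacers; the first ``guides_per_gene``
    (resp. ``ntc_count``) are taken in order.  Guides are split into three
    selection groups of equal size by rank order, mirroring a three-criterion
    guide-selection scheme.
    """
    elements: list[GuideElement] = []
    seen_spacers: dict[str, str] = {}

    def register(spacer: str, eid: str) -> str:
        spacer = _check_spacer(spacer, eid)
        if spacer in seen_spacers:
            raise LibraryError(
                f"duplicate spacer shared by {seen_spacers[spacer]} and {eid}"
            )
        seen_spacers[spacer] = eid
        return spacer

    for gene in genes:
        if gene == NTC:
            raise LibraryError("'NTC' is reserved and cannot be a gene symbol")
        pool = list(spacer_source.get(gene, ()))
        if len(pool) < guides_per_gene:
            raise LibraryError(
                f"gene {gene!r} provides {len(pool)} spacers, "
                f"needs {guides_per_gene}"
            )
        group_sizes = [len(part) for part in np.array_split(np.arange(guides_per_gene), 3)]
        idx = 0
        for group, size in enumerate(group_sizes, start=1):
            for rank in range(1, size + 1):
                eid = f"{gene}_g{idx + 1:02d}"
                elements.append(
                    GuideElement(eid, gene, register(pool[idx], eid), group, rank)
                )
                idx += 1

    ntc_pool = list(spacer_source.get(NTC, ()))
    if len(ntc_pool) < ntc_count:
        raise LibraryError(
            f"NTC pool provides {len(ntc_pool)} spacers, needs {ntc_count}"
        )
    for i in range(ntc_count):
        eid = f"NTC_{i + 1:02d}"
        elements.append(GuideElement(eid, NTC, register(ntc_pool[i], eid), 1, i + 1))
    return elements


def build_arrays(
    guide_set: Sequence[GuideElement],
    arrays_per_gene: int,
    ntc_arrays: int,
    seed: int,
) -> list[GuideArray]:
    """Compile single guides into 3-guide arrays.

    Gene array *k* concatenates the rank-*k* guide of each of the three
    selection groups, preserving group balance.  NTC arrays are random
    3-subsets of the NTC guides drawn without replacement.
    """
    arrays: list[GuideArray] = []
    by_gene: dict[str, list[GuideElement]] = {}
    ntcs: list[GuideElement] = []
    for e in guide_set:
        (ntcs if e.is_ntc else by_gene.setdefault(e.target, [])).append(e)

    for gene, guides in by_gene.items():
        if len(guides) != 3 * arrays_per_gene:
            raise LibraryError(
                f"gene {gene!r} has {len(guides)} guides; "
                f"{3 * arrays_per_gene} required for {arrays_per_gene} arrays"
            )
        by_group: dict[int, dict[int, GuideElement]] = {}
        for g in guides:
            by_group.setdefault(g.group, {})[g.rank] = g
        if sorted(by_group) != [1, 2, 3]:
            raise LibraryError(f"gene {gene!r} guides do not span groups 1-3")
        for k in range(1, arrays_per_gene + 1):
            members = tuple(by_group[grp][k] for grp in (1, 2, 3))
            arrays.append(
                GuideArray(
                    element_id=f"{gene}_a{k}",
                    target=gene,
                    members=tuple(m.element_id for m in members),
                    spacers=tuple(m.spacer for m in members),
                )
            )

    if 3 * ntc_arrays > len(ntcs):
        raise LibraryError(
            f"{ntc_arrays} NTC arrays need {3 * ntc_arrays} NTC guides, "
            f"have {len(ntcs)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ntcs))
    for k in range(ntc_arrays):
        trio = [ntcs[i] for i in order[3 * k : 3 * k + 3]]
        arrays.append(
            GuideArray(
                element_id=f"NTC_a{k + 1}",
                target=NTC,
                members=tuple(m.element_id for m in trio),
                spacers=tuple(m.spacer for m in trio),
            )
        )
    return arrays


def build_library(elements: Sequence, strategy: str, dr36: str = DR36) -> LibraryDesign:
    """Enumerate all constructs of a strategy from an element set.

    Dual-promoter strategies produce the full ordered cross (|elements|^2
    constructs).  The concatenated ``U6-g1-g2`` strategy pairs every element
    with every NTC in each of the two positions, giving
    ``2 x |elements| x |NTC|`` constructs; NTC-NTC pairs occur once per
    position block and are kept as distinct cloning products.
    """
    if strategy not in STRATEGIES:
        raise LibraryError(f"unknown strategy {strategy!r}")
    kinds = {e.element_kind for e in elements}
    if len(kinds) != 1:
        raise LibraryError(f"mixed element kinds {sorted(kinds)} in one library")
    kind = kinds.pop()
    if strategy == "U6-a1-U6-a2" and kind != "array":
        raise LibraryError("array strategy requires array elements")
    if strategy != "U6-a1-U6-a2" and kind != "guide":
        raise LibraryError(f"strategy {strategy} requires single-guide elements")

    targets = {e.element_id: e.target for e in elements}
    constructs: list[Construct] = []

    def add(p1: str, p2: str, suffix: str = "") -> None:
        constructs.append(
            Construct(
                construct_id=f"{p1}--{p2}{suffix}",
                pos1=p1,
                pos2=p2,
                pair_class=_pair_class(targets[p1], targets[p2]),
            )
        )

    ids = [e.element_id for e in elements]
    if strategy in ("U6-g1-U6-g2", "U6-a1-U6-a2"):
        for p1, p2 in itertools.product(ids, ids):
            add(p1, p2)
    else:  # U6-g1-g2
        ntc_ids = [e.element_id for e in elements if e.is_ntc]
        if not ntc_ids:
            raise LibraryError("concatenated strategy requires NTC elements")
        for p1 in ids:
            for p2 in ntc_ids:
                add(p1, p2)
        for p1 in ntc_ids:
            for p2 in ids:
                # NTC-NTC pairs recur in this block; tag to keep ids unique.
                add(p1, p2, suffix="--r" if targets[p2] == NTC else "")
    return LibraryDesign(strategy=strategy, elements=list(elements), constructs=constructs, dr36=dr36)


def render_oligo(construct: Construct, library: LibraryDesign) -> str:
    """Render the synthesis oligo for one construct under its strategy."""
    e1 = library.element(construct.pos1)
    e2 = library.element(construct.pos2)
    dr = library.dr36
    if library.strategy == "U6-g1-g2":
        for e in (e1, e2):
            if e.element_kind != "guide":
                raise LibraryError("concatenated strategy renders single guides only")
        p1 = CONCAT_P1_PREFIX + dr + e1.spacer + CONCAT_P1_SUFFIX
        p2 = CONCAT_P2_PREFIX + e2.spacer + dr + CONCAT_P2_SUFFIX
        return p1 + p2
    if library.strategy == "U6-g1-U6-g2":
        return (
            DUAL_PREFIX + e1.spacer + DUAL_SUFFIX
            + DUAL_PREFIX + e2.spacer + DUAL_SUFFIX
        )
    # U6-a1-U6-a2
    for e in (e1, e2):
        if e.element_kind != "array":
            raise LibraryError("array strategy renders arrays only")
    return (
        DUAL_PREFIX + e1.rendered_insert(dr) + DUAL_SUFFIX
        + DUAL_PREFIX + e2.rendered_insert(dr) + DUAL_SUFFIX
    )


def random_spacer_table(
    genes: Sequence[str],
    per_gene: int,
    ntc_count: int,
    seed: int,
    avoid: Sequence[str] = (),
) -> dict[str, list[str]]:
    """Generate a unique random spacer table for simulations and fixtures.

    ``avoid`` lists motifs (e.g. recombination diagnostics) that must not
    occur in any spacer.
    """
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    table: dict[str, list[str]] = {}
    for key, n in [(g, per_gene) for g in genes] + [(NTC, ntc_count)]:
        pool: list[str] = []
        while len(pool) < n:
            s = "".join(rng.choice(bases, size=SPACER_LEN))
            if s in seen or any(m in s for m in avoid):
                continue
            seen.add(s)
            pool.append(s)
        table[key] = pool
    return table
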