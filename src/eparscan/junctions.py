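"""Typing of recombinant LTR6B junction elements.

The ePAR (extended pseudoautosomal region) and its reciprocal X deletion
are both products of a single non-allelic homologous recombination (NAHR)
crossover between two ~550-bp LTR6B elements: one inside PAR1 on the Y
("Y-PAR element") and one in normally X-specific sequence.  A sequenced
junction element is therefore a mosaic: distal of the crossover it matches
one parent, proximal of it the other.  This module maps junction sequences
onto a catalog of variant positions in the 559-bp maximal alignment of the
two parents, deduplicates them into junction types, localizes the crossover
to the interval between flanking informative positions, counts distinct
rearranged chromosomes, and tests for biased allele sharing between the
parental elements.

Coordinates are 1-based along the 559-bp alignment, position 1 being the
distal (5') end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CatalogSite",
    "VariantCatalog",
    "LengthSite",
    "LTR6BModel",
    "JunctionObservation",
    "JunctionType",
    "JunctionTypeRegistry",
    "CrossoverInterval",
    "GeneConversionError",
    "map_to_references",
    "classify_junction_types",
    "infer_crossover_interval",
    "distinct_rearranged_chromosomes",
    "allele_sharing_table",
    "allele_sharing_test",
]

ALLOWED_LENGTH_CLASSES = (551, 554, 559)


class GeneConversionError(ValueError):
    """Interleaved parental states incompatible with a single crossover.

    A single crossover produces one block of each parental state.  A
    derived-state position of one parent lying distal to one of the other
    parent (beyond zero tolerance) suggests gene conversion or a complex
    exchange and is flagged rather than silently truncated.
    """


@dataclass(frozen=True)
class CatalogSite:
    """One variant position of the X / Y-PAR element alignment.

    ``x_alleles`` and ``y_alleles`` map allele -> frequency on the
    respective parental element.  A fixed difference (paralogous sequence
    variant) is a site whose parental allele sets are disjoint.
    """

    position: int
    x_alleles: Mapping[str, float]
    y_alleles: Mapping[str, float]

    def __post_init__(self):
        for alleles in (self.x_alleles, self.y_alleles):
            total = sum(alleles.values())
            if alleles and not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(
                    f"allele frequencies at position {self.position} sum to {total}"
                )

    @property
    def fixed_difference(self) -> bool:
        return not (set(self.x_alleles) & set(self.y_alleles))

    @staticmethod
    def _major(alleles: Mapping[str, float]) -> str:
        # deterministic tie-break on allele string
        return max(sorted(alleles), key=lambda a: alleles[a])

    @staticmethod
    def _minor(alleles: Mapping[str, float]) -> str | None:
        """Lowest-frequency allele, or None for a monomorphic site."""
        if len(alleles) < 2:
            return None
        return min(sorted(alleles), key=lambda a: alleles[a])

    @property
    def x_major(self) -> str:
        return self._major(self.x_alleles)

    @property
    def y_major(self) -> str:
        return self._major(self.y_alleles)


class VariantCatalog:
    """Ordered collection of :class:`CatalogSite` in element coordinates."""

    def __init__(self, sites: Iterable[CatalogSite]):
        self.sites = sorted(sites, key=lambda s: s.position)
        positions = [s.position for s in self.sites]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate catalog positions")

    def __iter__(self):
        return iter(self.sites)

    def __len__(self):
        return len(self.sites)

    def site(self, position: int) -> CatalogSite:
        for s in self.sites:
            if s.position == position:
                return s
        raise KeyError(f"no catalog site at position {position}")

    def fixed_sites(self) -> list[CatalogSite]:
        return [s for s in self.sites if s.fixed_difference]

    def shared_sites(self) -> list[CatalogSite]:
        return [s for s in self.sites if not s.fixed_difference]

    def major_diff_sites(self) -> list[CatalogSite]:
        """Sites whose parental major alleles differ (includes fixed sites)."""
        return [s for s in self.sites if s.x_major != s.y_major]


@dataclass(frozen=True)
class LengthSite:
    """One of the two variable-length sites of the element.

    ``span`` alignment columns starting at ``start`` (1-based) hold the
    longest allele; shorter alleles are padded with ``-`` on the proximal
    side.  Allele sets are stored, not derived, because not every length
    combination is observed in nature.
    """

    name: str
    start: int
    alleles: frozenset[str]

    @property
    def span(self) -> int:
        return max(len(a) for a in self.alleles)

    @property
    def end(self) -> int:
        return self.start + self.span - 1

    def pad(self, allele: str) -> str:
        if allele not in self.alleles:
            raise ValueError(f"{allele!r} is not an allowed {self.name} length allele")
        return allele + "-" * (self.span - len(allele))


@dataclass
class LTR6BModel:
    """The two parental LTR6B elements with their variant catalog.

    Parental sequences are stored gapped in the common alignment frame so
    that every catalog position indexes both identically.
    """

    x_element: str
    y_element: str
    catalog: VariantCatalog
    length_sites: tuple[LengthSite, LengthSite]

    def __post_init__(self):
        if len(self.x_element) != len(self.y_element):
            raise ValueError("parental elements must share the alignment frame")
        n = len(self.x_element)
        for s in self.catalog:
            if not 1 <= s.position <= n:
                raise ValueError(f"catalog position {s.position} outside alignment")

    @property
    def alignment_length(self) -> int:
        return len(self.x_element)

    def allowed_total_lengths(self) -> set[int]:
        base = self.alignment_length - sum(ls.span for ls in self.length_sites)
        combos = itertools.product(*(sorted(ls.alleles) for ls in self.length_sites))
        totals = {base + sum(len(a) for a in alleles) for alleles in combos}
        return {t for t in totals if t in ALLOWED_LENGTH_CLASSES}


@dataclass
class JunctionObservation:
    """A sequenced recombinant element mapped onto the catalog frame.

    ``states`` gives the parental assignment per catalog position: ``"X"``
    (base private to the X element), ``"Y"``, ``"shared"`` (carried by
    both parents) or ``"missing"``.  ``role`` distinguishes the two NAHR
    products: an ePAR junction carries the X-derived segment distally and
    the Y-PAR segment proximally; a deletion junction is the reverse.
    Deletion junctions may additionally carry a flanking-SNP haplotype
    (rs311159 and rs2109378 in the Y-PAR-derived distal flank, rs211658 in
    the X-derived proximal flank), which lies outside element coordinates.
    """

    sample_id: str
    sequence: str
    aligned: str
    states: dict[int, str]
    bases: dict[int, str]
    length_class: int
    role: str = "EPAR"
    flanking: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.role not in ("EPAR", "DELETION"):
            raise ValueError(f"unknown junction role {self.role!r}")
        if self.length_class not in ALLOWED_LENGTH_CLASSES:
            raise ValueError(f"length class {self.length_class} not in "
                             f"{ALLOWED_LENGTH_CLASSES}")


def map_to_references(
    sequence: str,
    model: LTR6BModel,
    sample_id: str = "",
    role: str = "EPAR",
    flanking: tuple[str, ...] | None = None,
) -> JunctionObservation:
    """Place a junction sequence in the alignment frame and call states.

    Gapped alignment is restricted to the two variable-length sites: the
    candidate length-allele combinations compatible with the observed total
    length are tried, each must reproduce the observed bases at its site,
    and the candidate maximizing matches to either parent wins.
    """
    n = len(sequence)
    allowed = model.allowed_total_lengths()
    if n not in allowed:
        raise ValueError(
            f"junction length {n} bp outside the allowed classes {sorted(allowed)}"
        )
    base_len = model.alignment_length - sum(ls.span for ls in model.length_sites)
    candidates = []
    for alleles in itertools.product(
        *(sorted(ls.alleles) for ls in model.length_sites)
    ):
        if base_len + sum(len(a) for a in alleles) != n:
            continue
        aligned = _gap_sequence(sequence, model.length_sites, alleles)
        if aligned is not None:
            candidates.append(aligned)
    if not candidates:
        raise ValueError(
            f"no length-allele combination reproduces the {n}-bp sequence"
        )

    def score(aligned: str) -> int:
        return sum(
            a == x or a == y
            for a, x, y in zip(aligned, model.x_element, model.y_element)
        )

    aligned = max(candidates, key=score)
    states, bases = {}, {}
    for site in model.catalog:
        base = aligned[site.position - 1]
        bases[site.position] = base
        in_x = base in site.x_alleles
        in_y = base in site.y_alleles
        if in_x and in_y:
            states[site.position] = "shared"
        elif in_x:
            states[site.position] = "X"
        elif in_y:
            states[site.position] = "Y"
        else:
            states[site.position] = "missing"
    return JunctionObservation(
        sample_id=sample_id,
        sequence=sequence,
        aligned=aligned,
        states=states,
        bases=bases,
        length_class=n,
        role=role,
        flanking=flanking,
    )


def _gap_sequence(
    sequence: str, length_sites: Sequence[LengthSite], alleles: Sequence[str]
) -> str | None:
    """Insert gaps for the given length-allele combination; None on mismatch.

    Padding each site back to its full span restores the alignment frame,
    so downstream sites are addressed at their frame coordinates.
    """
    aligned = sequence
    for site, allele in zip(sorted(length_sites, key=lambda s: s.start), alleles):
        start = site.start - 1
        observed = aligned[start : start + len(allele)]
        if observed != allele:
            return None
        aligned = aligned[: start + len(allele)] + "-" * (
            site.span - len(allele)
        ) + aligned[start + len(allele) :]
    return aligned


# ---------------------------------------------------------------------------
# junction type registry


@dataclass
class JunctionType:
    type_id: str
    canonical_sequence: str
    members: list[str] = field(default_factory=list)


class JunctionTypeRegistry:
    """Exact-sequence junction types in first-seen order.

    Published types (e.g. the two junctions known before the biobank
    screen, Junc1 and Junc2) are matched first by canonical sequence; new
    types continue the numbering (Junc3, Junc4, ...).
    """

    def __init__(self, types: list[JunctionType], assignments: dict[str, str]):
        self.types = types
        self.assignments = assignments  # sample_id -> type_id
        seqs = [t.canonical_sequence for t in types]
        if len(set(seqs)) != len(seqs):
            raise ValueError("canonical sequences must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.types)

    def type(self, type_id: str) -> JunctionType:
        for t in self.types:
            if t.type_id == type_id:
                return t
        raise KeyError(type_id)

    def counts(self) -> dict[str, int]:
        return {t.type_id: len(t.members) for t in self.types}


def classify_junction_types(
    observations: Sequence[JunctionObservation],
    published: Mapping[str, str] | None = None,
    prefix: str = "Junc",
    sort_canonical: bool = False,
) -> JunctionTypeRegistry:
    """Deduplicate junction observations into exact-sequence types.

    ``published`` maps known type ids to their canonical sequences; they
    claim matching observations before new ids are assigned.  With
    ``sort_canonical`` the observations are processed in sorted-sequence
    order so that new-type ids are independent of input order.
    """
    if not observations:
        raise ValueError("no observations to classify")
    published = dict(published or {})
    by_seq: dict[str, JunctionType] = {}
    types: list[JunctionType] = []
    for type_id, seq in published.items():
        t = JunctionType(type_id=type_id, canonical_sequence=seq)
        by_seq[seq] = t
        types.append(t)
    next_index = len(published) + 1
    ordered = (
        sorted(observations, key=lambda o: (o.sequence, o.sample_id))
        if sort_canonical
        else list(observations)
    )
    assignments: dict[str, str] = {}
    for obs in ordered:
        t = by_seq.get(obs.sequence)
        if t is None:
            t = JunctionType(
                type_id=f"{prefix}{next_index}", canonical_sequence=obs.sequence
            )
            next_index += 1
            by_seq[obs.sequence] = t
            types.append(t)
        t.members.append(obs.sample_id)
        assignments[obs.sample_id] = t.type_id
    # published types with no members are dropped from the registry
    types = [t for t in types if t.members or t.type_id not in published]
    return JunctionTypeRegistry(types, assignments)


# ---------------------------------------------------------------------------
# crossover interval inference


@dataclass(frozen=True)
class CrossoverInterval:
    """Open interval bounding the NAHR exchange point.

    ``lo``/``hi`` are informative catalog positions (None when the
    corresponding side carries no informative state, in which case the
    interval is indeterminate on that side).
    """

    lo: int | None
    hi: int | None
    mode: str
    status: str = "bounded"

    def __post_init__(self):
        if self.lo is not None and self.hi is not None and not self.lo < self.hi:
            raise ValueError("lower bound must be below upper bound")

    @property
    def width(self) -> int | None:
        if self.lo is None or self.hi is None:
            return None
        return self.hi - self.lo

    def contains(self, c: float) -> bool:
        lo = -np.inf if self.lo is None else self.lo
        hi = np.inf if self.hi is None else self.hi
        return lo < c <= hi


def infer_crossover_interval(
    observation: JunctionObservation,
    catalog: VariantCatalog,
    mode: str = "FIXED_ONLY",
) -> CrossoverInterval:
    """Bound the crossover between the flanking informative positions.

    FIXED_ONLY uses fixed differences only; MAJOR_ALLELE also uses sites
    where the parental major alleles differ, assigning a side by matching
    the observed base to a parental major allele.  For an ePAR-role
    junction the crossover lies in (last distal-parent position, first
    proximal-parent position) with X distal; a deletion junction swaps the
    parental roles.
    """
    if mode not in ("FIXED_ONLY", "MAJOR_ALLELE"):
        raise ValueError(f"unknown mode {mode!r}")
    sites = catalog.fixed_sites() if mode == "FIXED_ONLY" else catalog.major_diff_sites()
    distal_parent = "X" if observation.role == "EPAR" else "Y"
    proximal_parent = "Y" if observation.role == "EPAR" else "X"
    distal_positions, proximal_positions = [], []
    for site in sites:
        side = _side_call(observation, site, mode)
        if side == distal_parent:
            distal_positions.append(site.position)
        elif side == proximal_parent:
            proximal_positions.append(site.position)
    lo = max(distal_positions) if distal_positions else None
    hi = min(proximal_positions) if proximal_positions else None
    if lo is not None and hi is not None and lo > hi:
        raise GeneConversionError(
            f"{observation.sample_id or 'junction'}: {distal_parent}-state at "
            f"position {lo} proximal to {proximal_parent}-state at {hi}; "
            "pattern incompatible with a single crossover (possible gene "
            "conversion)"
        )
    status = "bounded" if lo is not None and hi is not None else "indeterminate"
    return CrossoverInterval(lo=lo, hi=hi, mode=mode, status=status)


def _side_call(obs: JunctionObservation, site: CatalogSite, mode: str) -> str | None:
    if mode == "FIXED_ONLY":
        state = obs.states.get(site.position)
        return state if state in ("X", "Y") else None
    base = obs.bases.get(site.position)
    if base is None or base == "-":
        return None
    xm, ym = site.x_major, site.y_major
    if base == xm and base != ym:
        return "X"
    if base == ym and base != xm:
        return "Y"
    return None


# ---------------------------------------------------------------------------
# distinct rearranged chromosomes


def distinct_rearranged_chromosomes(
    observations: Sequence[JunctionObservation],
    published: Mapping[str, str] | None = None,
) -> tuple[int, dict[tuple, list[str]]]:
    """Count distinct rearranged chromosomes among same-role junctions.

    Two observations belong to the same chromosome class when they share
    both the junction type (exact sequence) and the flanking-SNP haplotype;
    flanking information splits otherwise identical junction types.
    """
    roles = {o.role for o in observations}
    if len(roles) > 1:
        raise ValueError(f"observations mix roles {sorted(roles)}")
    registry = classify_junction_types(observations, published=published)
    partition: dict[tuple, list[str]] = {}
    for obs in observations:
        key = (registry.assignments[obs.sample_id], obs.flanking)
        partition.setdefault(key, []).append(obs.sample_id)
    return len(partition), partition


# ---------------------------------------------------------------------------
# allele-sharing asymmetry


def allele_sharing_table(catalog: VariantCatalog) -> np.ndarray:
    """Cross-classify shared-polymorphism sites by allele-sharing pattern.

    Rows: X-element minor allele equals the Y-element major allele
    (yes / no); columns: the reverse relation.  A monomorphic element has
    no minor allele, so the corresponding relation is "no".
    """
    shared = catalog.shared_sites()
    if not shared:
        raise ValueError("catalog has no shared-polymorphism sites")
    table = np.zeros((2, 2), dtype=int)
    for site in shared:
        x_minor = CatalogSite._minor(site.x_alleles)
        y_minor = CatalogSite._minor(site.y_alleles)
        p = x_minor is not None and x_minor == site.y_major
        q = y_minor is not None and y_minor == site.x_major
        table[0 if p else 1, 0 if q else 1] += 1
    return table


def allele_sharing_test(catalog_or_table) -> float:
    """One-tailed Fisher exact test of allele-sharing asymmetry.

    Accepts a :class:`VariantCatalog` (the 2x2 table is built from its
    shared-polymorphism sites) or a ready-made 2x2 table.  Returns the
    exact upper (hypergeometric) tail probability; degenerate margins give
    p = 1 by convention.
    """
    if isinstance(catalog_or_table, VariantCatalog):
        table = allele_sharing_table(catalog_or_table)
    else:
        table = np.asarray(catalog_or_table, dtype=int)
        if table.shape != (2, 2) or (table < 0).any():
            raise ValueError("expected a non-negative 2x2 table")
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(table, alternative="greater")[1])
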