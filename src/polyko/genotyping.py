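"""Mutant allele calling, naming and chimerism assessment.

NHEJ repair of a Cas9 cut leaves small insertions or deletions at the
cut site.  Reads (Sanger amplicons or plasmid clones) are globally
aligned to the wild-type reference with affine gap penalties, indels
are left-normalised (VCF-style leftmost placement, so allele identity
is well defined inside homopolymers), and events are reported relative
to the cut site.  Alleles are then given the pedigree letter codes used
for multi-locus knockout experiments: the wild-type allele at locus X
is ``Xh`` and edited alleles are numbered ``X1``, ``X2``, ... in order
of first observation.

A primary transformant is frequently chimeric — ongoing somatic editing
leaves more than two distinct alleles at a locus; :func:`assess_chimerism`
quantifies this from a set of clone sequences.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from Bio import Align

from polyko.guides import GuideCandidate, locate_guide

__all__ = [
    "IndelEvent",
    "AlleleCall",
    "ChimerismResult",
    "ForeignAmpliconError",
    "call_alleles",
    "apply_events",
    "name_alleles",
    "assess_chimerism",
    "genotype_plant",
    "composite_label",
]


class ForeignAmpliconError(ValueError):
    """Raised when a read does not plausibly derive from the reference."""


@dataclass(frozen=True)
class IndelEvent:
    """A single indel, positioned relative to the cut site.

    ``position`` is the reference coordinate of the event minus the cut
    coordinate (0 = at the cut).  Deletions carry an empty sequence.
    """

    position: int
    kind: str  # "insertion" | "deletion"
    length: int
    sequence: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion"):
            raise ValueError(f"bad event kind {self.kind!r}")
        if self.kind == "deletion" and self.sequence:
            raise ValueError("deletion events carry no sequence")
        if self.kind == "insertion" and len(self.sequence) != self.length:
            raise ValueError("insertion sequence length mismatch")


@dataclass
class AlleleCall:
    """Events and coding consequence of one read at one locus."""

    locus_code: str
    events: tuple[IndelEvent, ...]
    frame_consequence: str  # "frameshift" | "in-frame" | "none"
    allele_code: str = ""
    n_substitutions: int = 0

    @property
    def is_wild_type(self) -> bool:
        return not self.events


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -4
    a.open_gap_score = -10
    a.extend_gap_score = -0.5
    return a


def _left_normalise_deletion(ref: str, start: int, length: int) -> int:
    """Shift a deletion of ref[start:start+length] to its leftmost placement."""
    while start > 0 and ref[start - 1] == ref[start + length - 1]:
        start -= 1
    return start


def _left_normalise_insertion(ref: str, pos: int, seq: str) -> tuple[int, str]:
    """Shift an insertion before ref[pos] to its leftmost equivalent."""
    while pos > 0 and ref[pos - 1] == seq[-1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def _frame_consequence(events: tuple[IndelEvent, ...], coding: bool) -> str:
    if not events or not coding:
        return "none"
    net = sum(e.length if e.kind == "insertion" else -e.length for e in events)
    return "in-frame" if net % 3 == 0 else "frameshift"


def call_alleles(
    read_seq: str,
    reference_seq: str,
    guide: GuideCandidate | None = None,
    cut_site: int | None = None,
    locus_code: str = "X",
    coding: bool = True,
    min_identity: float = 0.8,
    max_noise_substitutions: int = 2,
    noise_window: int = 30,
) -> AlleleCall:
    """Call indel events in a read against the wild-type reference.

    The read is globally aligned with affine gap penalties; indels are
    left-normalised and reported relative to the cut site (taken from
    ``guide`` or given directly as ``cut_site``).  Substitutions are
    treated as sequencing noise: up to ``max_noise_substitutions`` are
    tolerated outside a ±``noise_window`` nt window around the cut,
    beyond which the read is rejected.  Reads aligning below
    ``min_identity`` raise :class:`ForeignAmpliconError`.
    """
    read_seq = read_seq.upper()
    reference_seq = reference_seq.upper()
    if cut_site is None:
        if guide is None:
            raise ValueError("need a guide or an explicit cut_site")
        cut_site, _ = locate_guide(reference_seq, guide)

    aln = _aligner().align(reference_seq, read_seq)[0]
    ref_blocks, read_blocks = aln.aligned

    matches = 0
    columns = 0
    substitutions: list[int] = []
    raw_events: list[tuple[str, int, int, str]] = []  # kind, ref pos, length, seq

    prev_r = prev_q = 0
    for (r0, r1), (q0, q1) in zip(ref_blocks, read_blocks):
        if r0 > prev_r:  # deletion from the reference
            raw_events.append(("deletion", prev_r, r0 - prev_r, ""))
            columns += r0 - prev_r
        if q0 > prev_q:  # insertion in the read
            raw_events.append(("insertion", r0, q0 - prev_q, read_seq[prev_q:q0]))
            columns += q0 - prev_q
        for rr, qq in zip(range(r0, r1), range(q0, q1)):
            columns += 1
            if reference_seq[rr] == read_seq[qq]:
                matches += 1
            else:
                substitutions.append(rr)
        prev_r, prev_q = r1, q1
    # terminal gaps
    columns += (len(reference_seq) - prev_r) + (len(read_seq) - prev_q)
    if len(reference_seq) - prev_r:
        raw_events.append(("deletion", prev_r, len(reference_seq) - prev_r, ""))
    if len(read_seq) - prev_q:
        raw_events.append(("insertion", len(reference_seq), len(read_seq) - prev_q,
                           read_seq[prev_q:]))

    if columns == 0 or matches / columns < min_identity:
        raise ForeignAmpliconError(
            f"read identity {matches / max(columns, 1):.2f} below floor {min_identity}"
        )

    noise = [p for p in substitutions if abs(p - cut_site) > noise_window]
    if len(noise) > max_noise_substitutions:
        raise ForeignAmpliconError(
            f"{len(noise)} substitutions outside the cut window exceed the "
            f"noise tolerance ({max_noise_substitutions})"
        )

    events = []
    for kind, pos, length, seq in raw_events:
        if kind == "deletion":
            pos = _left_normalise_deletion(reference_seq, pos, length)
        else:
            pos, seq = _left_normalise_insertion(reference_seq, pos, seq)
        events.append(IndelEvent(pos - cut_site, kind, length, seq))
    events = tuple(sorted(events, key=lambda e: (e.position, e.kind, e.length)))

    return AlleleCall(
        locus_code=locus_code,
        events=events,
        frame_consequence=_frame_consequence(events, coding),
        n_substitutions=len(substitutions),
    )


def apply_events(reference_seq: str, events: tuple[IndelEvent, ...], cut_site: int) -> str:
    """Reconstruct an allele sequence from its event list.

    Inverse of :func:`call_alleles` for noiseless reads; used for
    round-trip checking.
    """
    seq = reference_seq.upper()
    for e in sorted(events, key=lambda e: -e.position):
        pos = e.position + cut_site
        if e.kind == "deletion":
            seq = seq[:pos] + seq[pos + e.length :]
        else:
            seq = seq[:pos] + e.sequence + seq[pos:]
    return seq


def name_alleles(calls_by_locus: dict[str, list[AlleleCall]]) -> dict[str, dict[tuple, str]]:
    """Assign stable letter+number codes to distinct alleles per locus.

    Identical event lists share one code.  Wild type is always
    ``<locus>h``; mutants are numbered in order of first observation,
    which makes the mapping a pure function of the ordered input.
    ``allele_code`` is set on every call in place; the event-list ->
    code mapping per locus is returned.
    """
    codings: dict[str, dict[tuple, str]] = {}
    for locus, calls in calls_by_locus.items():
        mapping: dict[tuple, str] = {(): f"{locus}h"}
        counter = 0
        for call in calls:
            key = call.events
            if key not in mapping:
                counter += 1
                mapping[key] = f"{locus}{counter}"
            call.allele_code = mapping[key]
        codings[locus] = mapping
    return codings


@dataclass
class ChimerismResult:
    """Summary of clone sequencing at one locus of one plant."""

    n_mutant_alleles: int
    n_total_alleles: int
    edited_fraction: float
    chimeric: bool
    saturation_warning: bool
    allele_counts: Counter = field(default_factory=Counter)


def assess_chimerism(
    clone_seqs: list[str],
    reference_seq: str,
    guide: GuideCandidate | None = None,
    cut_site: int | None = None,
    locus_code: str = "X",
) -> ChimerismResult:
    """Count distinct alleles among plasmid clone sequences at one locus.

    More than two distinct alleles in total flags the plant as chimeric
    (ongoing somatic editing in the primary transformant).  When clone
    coverage is thin relative to allele diversity, the distinct-allele
    count may undershoot; a saturation warning is raised when fewer
    than two clones per observed allele were sequenced.
    """
    if not clone_seqs:
        raise ValueError("need at least one clone sequence")
    calls = [
        call_alleles(s, reference_seq, guide=guide, cut_site=cut_site,
                     locus_code=locus_code)
        for s in clone_seqs
    ]
    counts: Counter = Counter(c.events for c in calls)
    n_total = len(counts)
    n_mutant = sum(1 for k in counts if k)
    edited = sum(v for k, v in counts.items() if k) / len(calls)
    return ChimerismResult(
        n_mutant_alleles=n_mutant,
        n_total_alleles=n_total,
        edited_fraction=edited,
        chimeric=n_total > 2,
        saturation_warning=len(clone_seqs) < 2 * n_total,
        allele_counts=counts,
    )


_ZYGOSITY_LABELS = {1: "single", 2: "double", 3: "triple", 4: "quadruple"}


def zygosity(allele_pair: tuple[str, str]) -> str:
    """Classify a two-allele genotype at one locus.

    Wild-type alleles carry the ``h`` suffix.
    """
    a, b = allele_pair
    wa, wb = a.endswith("h"), b.endswith("h")
    if wa and wb:
        return "homozygous_wt"
    if wa or wb:
        return "heterozygous"
    if a == b:
        return "homozygous_mutant"
    return "biallelic_mutant"


def composite_label(loci_zygosity: dict[str, str], required_loci: list[str]) -> str:
    """Multi-locus label over a supplied locus set.

    A plant homozygous mutant at k of the required loci is a
    "<k>-fold mutant" ("triple mutant" for k = 3); zero gives
    "wild type" semantics over that set.
    """
    k = sum(
        1 for locus in required_loci
        if loci_zygosity.get(locus) == "homozygous_mutant"
    )
    if k == 0:
        return "wild type"
    word = _ZYGOSITY_LABELS.get(k, f"{k}-fold")
    return f"{word} mutant"


def genotype_plant(
    per_locus_alleles: dict[str, tuple[str, ...]],
    transgene_pcr: bool,
    plant_id: str = "",
    required_loci: list[str] | None = None,
):
    """Build a plant genotype from per-locus allele codes + transgene PCR.

    Each non-chimeric locus must carry one or two distinct alleles
    (singletons are read as homozygous); more than two raises an
    inconsistency error.  Returns a :class:`polyko.inheritance.PlantGenotype`
    with per-locus zygosity and, when ``required_loci`` is given, the
    composite mutant label in ``attrs['label']``.
    """
    from polyko.inheritance import PlantGenotype

    loci: dict[str, tuple[str, str]] = {}
    zyg: dict[str, str] = {}
    for locus, alleles in per_locus_alleles.items():
        distinct = tuple(dict.fromkeys(alleles))
        if len(distinct) > 2:
            raise ValueError(
                f"{len(distinct)} distinct alleles at locus {locus} without a "
                "chimeric flag"
            )
        pair = (distinct[0], distinct[1]) if len(distinct) == 2 \
            else (distinct[0], distinct[0])
        loci[locus] = pair
        zyg[locus] = zygosity(pair)

    plant = PlantGenotype(
        plant_id=plant_id or "plant", generation="T?", loci=dict(loci),
        transgenic=transgene_pcr,
    )
    plant.attrs["zygosity"] = zyg
    if required_loci is not None:
        plant.attrs["label"] = composite_label(zyg, required_loci)
    return plant
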