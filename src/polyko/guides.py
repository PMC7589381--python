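"""Family-conserved CRISPR-Cas9 guide design with off-target screening.

In a polyploid, a single sgRNA can knock out every copy of a gene family
at once — but only if the 20-nt protospacer is conserved across all
paralogs.  SpCas9 tolerates a single mismatch provided it lies outside
the PAM-proximal seed region (the ~10 nt next to the NGG PAM), so the
filter here accepts at most one mismatch per paralog and only at
protospacer positions 10-20 counted from the PAM.  Candidates also need
GC content strictly above 40% and no near-match hit elsewhere in the
genome.

Position convention: protospacer positions are counted 1..20 from the
PAM, position 1 being PAM-proximal.  In 5'->3' protospacer string
coordinates, position ``p`` from the PAM is string index ``20 - p``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib
import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from polyko._seq import encode, gc_percent, revcomp
from polyko.paralogs import GeneFamily, _CIGAR_RE

__all__ = [
    "GuideCandidate",
    "OffTargetHit",
    "locate_guide",
    "enumerate_sites",
    "score_conservation",
    "filter_candidates",
    "off_target_scan",
    "design_guides",
]

PROTOSPACER_LEN = 20
SITE_LEN = 23  # protospacer + NGG


def pos_from_pam(string_index: int) -> int:
    """Convert a 5'->3' protospacer string index (0..19) to 1..20 from PAM."""
    return PROTOSPACER_LEN - string_index


@dataclass
class OffTargetHit:
    contig: str
    start: int  # forward-strand start of the 23-nt site
    strand: str
    mismatches: int


@dataclass
class GuideCandidate:
    """A candidate protospacer+PAM with its per-paralog conservation profile.

    ``site_start``/``site_end`` delimit the 23-nt protospacer+PAM on the
    forward strand of the reference paralog; ``protospacer`` and ``pam``
    are 5'->3' on the guide strand.  ``mismatch_profiles`` maps each
    other paralog to the list of protospacer positions (1 = PAM-proximal)
    where it differs, or ``None`` when the homologous window is disrupted
    by gaps or lacks a valid NGG PAM (non-targetable).
    """

    protospacer: str
    pam: str
    reference_paralog: str
    site_start: int
    site_end: int
    strand: str
    gc_percent: float
    mismatch_profiles: dict[str, list[int] | None] = field(default_factory=dict)
    pam_profiles: dict[str, str | None] = field(default_factory=dict)
    off_target_hits: int | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if not re.fullmatch("[ACGT]GG", self.pam):
            raise ValueError(f"PAM must match NGG, got {self.pam!r}")

    @property
    def total_mismatches(self) -> int:
        return sum(len(v) for v in self.mismatch_profiles.values() if v)

    def cut_position(self, sequence: str | None = None) -> int:
        """Blunt-cut coordinate on the forward strand of the reference.

        SpCas9 cuts 3 bp PAM-proximal of the PAM (between protospacer
        positions 3 and 4 counted from the PAM).
        """
        if self.strand == "+":
            return self.site_end - 3 - 3  # 3 nt PAM + 3 nt to the cut
        return self.site_start + 6


def locate_guide(
    sequence: str, guide: GuideCandidate, max_mm: int = 3
) -> tuple[int, str]:
    """Find the guide's site in ``sequence``; return (cut index, strand).

    The cut index is a forward-strand coordinate: the cut falls between
    ``cut-1`` and ``cut``.  Exact occurrence is tried first; otherwise
    the best protospacer match with an intact GG PAM and at most
    ``max_mm`` mismatches is used (a guide is deliberately usable on a
    paralog that differs at a tolerated PAM-distal position).
    """
    sequence = sequence.upper()
    site = guide.protospacer + guide.pam
    i = sequence.find(site)
    if i >= 0:
        return i + PROTOSPACER_LEN - 3, "+"
    i = sequence.find(revcomp(site))
    if i >= 0:
        return i + 6, "-"
    proto_codes = encode(guide.protospacer)
    best: tuple[int, int, str] | None = None  # mm, cut, strand
    for start, mm in _scan_strand(encode(sequence), proto_codes, max_mm):
        cand = (mm, start + PROTOSPACER_LEN - 3, "+")
        if best is None or cand < best:
            best = cand
    rc = revcomp(sequence)
    for start, mm in _scan_strand(encode(rc), proto_codes, max_mm):
        fwd_start = len(sequence) - start - SITE_LEN
        cand = (mm, fwd_start + 6, "-")
        if best is None or cand < best:
            best = cand
    if best is None:
        raise ValueError("guide does not map onto the sequence")
    return best[1], best[2]


def enumerate_sites(sequence: str, reference_paralog: str = "") -> list[GuideCandidate]:
    """Every 20-mer immediately 5' of an NGG, on both strands.

    Coordinates are reported on the forward strand of the input.  GC
    content is computed; conservation profiles and off-target counts are
    left unset.
    """
    sequence = sequence.upper()
    sites: list[GuideCandidate] = []
    n = len(sequence)
    for i in range(n - SITE_LEN + 1):
        # forward: protospacer at [i, i+20), PAM at [i+20, i+23) = NGG
        if sequence[i + 21] == "G" and sequence[i + 22] == "G":
            proto = sequence[i : i + PROTOSPACER_LEN]
            pam = sequence[i + 20 : i + 23]
            if set(proto + pam) <= set("ACGT"):
                sites.append(
                    GuideCandidate(
                        protospacer=proto,
                        pam=pam,
                        reference_paralog=reference_paralog,
                        site_start=i,
                        site_end=i + SITE_LEN,
                        strand="+",
                        gc_percent=gc_percent(proto),
                    )
                )
        # reverse: CCN at [i, i+3) with the protospacer 3' of it
        if sequence[i] == "C" and sequence[i + 1] == "C":
            proto = revcomp(sequence[i + 3 : i + SITE_LEN])
            pam = revcomp(sequence[i : i + 3])
            if set(proto + pam) <= set("ACGT"):
                sites.append(
                    GuideCandidate(
                        protospacer=proto,
                        pam=pam,
                        reference_paralog=reference_paralog,
                        site_start=i,
                        site_end=i + SITE_LEN,
                        strand="-",
                        gc_percent=gc_percent(proto),
                    )
                )
    return sites


def _alignment_map(ref: str, other: str) -> list[int | None]:
    """Map each position of ``ref`` to its aligned position in ``other``.

    Positions aligned to a gap map to ``None``.  A ref position whose
    aligned neighbourhood contains an insertion in ``other`` still maps,
    but the window-contiguity check in :func:`score_conservation`
    catches the disruption.
    """
    res = edlib.align(ref, other, mode="NW", task="path")
    mapping: list[int | None] = [None] * len(ref)
    ri = oi = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        n = int(n)
        if op in "=XM":
            for _ in range(n):
                mapping[ri] = oi
                ri += 1
                oi += 1
        elif op == "D":  # present in ref, gap in other
            ri += n
        elif op == "I":  # insertion in other
            oi += n
    return mapping


def score_conservation(candidate: GuideCandidate, family: GeneFamily) -> GuideCandidate:
    """Fill in per-paralog mismatch profiles for ``candidate``.

    For each non-reference paralog, the homologous 23-nt window is
    located through the global alignment of the two CDSs.  A window
    disrupted by gaps (or non-contiguous) is recorded as non-targetable
    (profile ``None``); otherwise the differing protospacer positions
    (1 = PAM-proximal) and the paralog's PAM string are recorded.
    """
    ref = family.member(candidate.reference_paralog)
    refseq = ref.cds_sequence.upper()
    if refseq[candidate.site_start : candidate.site_end] not in (
        candidate.protospacer + candidate.pam,
        revcomp(candidate.protospacer + candidate.pam),
    ):
        raise ValueError("candidate does not locate on its reference paralog")

    for member in family.members:
        if member.id == ref.id:
            continue
        mapping = _alignment_map(refseq, member.cds_sequence.upper())
        window = mapping[candidate.site_start : candidate.site_end]
        contiguous = (
            all(p is not None for p in window)
            and all(b - a == 1 for a, b in zip(window, window[1:]))
        )
        if not contiguous:
            candidate.mismatch_profiles[member.id] = None
            candidate.pam_profiles[member.id] = None
            continue
        other_site = member.cds_sequence.upper()[window[0] : window[-1] + 1]
        if candidate.strand == "-":
            other_site = revcomp(other_site)
        other_proto, other_pam = other_site[:PROTOSPACER_LEN], other_site[PROTOSPACER_LEN:]
        if not re.fullmatch("[ACGT]GG", other_pam):
            # PAM ruined in this copy: Cas9 cannot target it at all
            candidate.mismatch_profiles[member.id] = None
            candidate.pam_profiles[member.id] = other_pam
            continue
        mismatches = [
            pos_from_pam(j)
            for j in range(PROTOSPACER_LEN)
            if other_proto[j] != candidate.protospacer[j]
        ]
        candidate.mismatch_profiles[member.id] = sorted(mismatches)
        candidate.pam_profiles[member.id] = other_pam
    return candidate


def filter_candidates(
    candidates: list[GuideCandidate],
    gc_min: float = 40.0,
    max_mismatches: int = 1,
    seed_boundary: int = 10,
) -> list[GuideCandidate]:
    """Apply the family-conservation filter.

    Keeps candidates with GC strictly above ``gc_min``, every paralog
    targetable, at most ``max_mismatches`` mismatches per paralog, all
    mismatches PAM-distal of the seed (position >= ``seed_boundary``
    from the PAM, boundary inclusive), and the PAM identical in every
    paralog.
    """
    accepted = []
    for c in candidates:
        if not c.gc_percent > gc_min:
            continue
        profiles = c.mismatch_profiles
        if any(v is None for v in profiles.values()):
            continue
        if any(len(v) > max_mismatches for v in profiles.values()):
            continue
        if any(p < seed_boundary for v in profiles.values() for p in v):
            continue
        if any(pam != c.pam for pam in c.pam_profiles.values()):
            continue
        accepted.append(c)
    return accepted


def _scan_strand(
    contig_codes: np.ndarray, proto_codes: np.ndarray, max_mm: int
) -> list[tuple[int, int]]:
    """(start, mismatches) of 23-nt windows matching protospacer+NGG."""
    if contig_codes.size < SITE_LEN:
        return []
    windows = sliding_window_view(contig_codes, SITE_LEN)
    mm = (windows[:, :PROTOSPACER_LEN] != proto_codes).sum(axis=1)
    valid = (
        (mm <= max_mm)
        & (windows[:, 21] == 2)  # G
        & (windows[:, 22] == 2)  # G
        & (windows[:, :PROTOSPACER_LEN] != 4).all(axis=1)
    )
    return [(int(i), int(mm[i])) for i in np.nonzero(valid)[0]]


def off_target_scan(
    candidate: GuideCandidate,
    genome_contigs: dict[str, str],
    family_intervals: list[tuple[str, int, int]],
    max_mm: int = 2,
) -> list[OffTargetHit]:
    """Scan the genome for near-matches of the candidate outside its family.

    Both strands are searched for 23-mers whose last two bases are GG
    (PAM N free) and whose first 20 bases differ from the protospacer at
    no more than ``max_mm`` positions.  Hits overlapping any interval in
    ``family_intervals`` (the on-target loci) are excluded.  The
    candidate passes the screen iff the returned list is empty; the hit
    count is stored on ``candidate.off_target_hits``.
    """
    if not genome_contigs:
        raise ValueError("empty genome")
    proto_codes = encode(candidate.protospacer)
    hits: list[OffTargetHit] = []
    for cname, contig in genome_contigs.items():
        codes = encode(contig.upper())
        clen = len(contig)
        for start, mm in _scan_strand(codes, proto_codes, max_mm):
            hits.append(OffTargetHit(cname, start, "+", mm))
        rc_codes = encode(revcomp(contig.upper()))
        for start, mm in _scan_strand(rc_codes, proto_codes, max_mm):
            hits.append(OffTargetHit(cname, clen - start - SITE_LEN, "-", mm))

    def on_target(h: OffTargetHit) -> bool:
        return any(
            h.contig == c and h.start < e and s < h.start + SITE_LEN
            for c, s, e in family_intervals
        )

    hits = [h for h in hits if not on_target(h)]
    candidate.off_target_hits = len(hits)
    return hits


def design_guides(
    family: GeneFamily,
    genome_contigs: dict[str, str],
    gc_min: float = 40.0,
    max_mismatches: int = 1,
    seed_boundary: int = 10,
    offtarget_mm: int = 2,
    reference_id: str | None = None,
    log: list[str] | None = None,
) -> list[GuideCandidate]:
    """End-to-end guide design for one gene family.

    Enumerates candidate sites on the reference paralog (the first
    member by default), scores conservation across the family, applies
    the seed/GC/PAM filter and the genome-wide off-target screen, and
    returns the survivors ranked by fewest total mismatches, then
    highest GC, then 5'-most position.  Deterministic for a fixed input.
    """
    if not family.members:
        raise ValueError("empty family")
    ref = family.member(reference_id) if reference_id else family.members[0]
    if log is None:
        log = []

    candidates = enumerate_sites(ref.cds_sequence, reference_paralog=ref.id)
    log.append(f"{family.name}: {len(candidates)} raw sites on {ref.id}")
    for c in candidates:
        score_conservation(c, family)
    kept = filter_candidates(
        candidates, gc_min=gc_min, max_mismatches=max_mismatches,
        seed_boundary=seed_boundary,
    )
    log.append(f"{family.name}: {len(kept)} sites pass the conservation filter")

    family_intervals = [(m.contig, m.start, m.end) for m in family.members]
    accepted = []
    for c in kept:
        hits = off_target_scan(c, genome_contigs, family_intervals, max_mm=offtarget_mm)
        if not hits:
            accepted.append(c)
    log.append(f"{family.name}: {len(accepted)} sites free of off-targets")
    if not accepted:
        log.append(f"{family.name}: design failed, no acceptable target site")

    accepted.sort(key=lambda c: (c.total_mismatches, -c.gc_percent, c.site_start))
    return accepted
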