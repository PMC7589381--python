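"""Allele and transgene tracking through selfing generations.

After a CRISPR transformation the T1 primary transformant is selfed for
several generations.  Three things matter for selecting the final
material: (i) whether the T-DNA segregates 3:1 (one hemizygous
insertion) so transgene-free offspring can be recovered, (ii) which
mutant alleles are actually germline-transmitted (chimeric T1 plants
may carry somatic-only alleles that vanish, while an active Cas9 can
create de novo alleles in T2), and (iii) which plants are homozygous
mutant at every required locus and transgene-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product

import pandas as pd
from scipy import stats

__all__ = [
    "PlantGenotype",
    "Pedigree",
    "SegregationResult",
    "InheritanceReport",
    "expected_segregation",
    "segregation_test",
    "track_alleles",
    "select_candidates",
]


@dataclass
class PlantGenotype:
    """One plant: per-locus alleles, transgene state, pedigree links.

    ``loci`` maps a locus code to its allele pair — or, for a chimeric
    plant, to the full tuple of clone-derived alleles (> 2 entries).
    Wild-type alleles carry the ``h`` suffix (``Ah``); edited alleles
    are numbered (``A1``).  ``tdna_count`` is the number of T-DNA
    copies at the (single) insertion locus: 1 = hemizygous.
    """

    plant_id: str
    generation: str
    loci: dict[str, tuple[str, ...]]
    transgenic: bool
    tdna_count: int | None = None
    parent_id: str | None = None
    germline: dict[str, tuple[str, ...]] | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tdna_count is None:
            self.tdna_count = 1 if self.transgenic else 0
        self.transgenic = self.tdna_count > 0

    @property
    def chimeric(self) -> bool:
        return any(len(set(a)) > 2 for a in self.loci.values())

    def allele_set(self, locus: str) -> set[str]:
        return set(self.loci[locus])

    def is_homozygous_mutant(self, locus: str) -> bool:
        alleles = set(self.loci[locus])
        return len(alleles) == 1 and not next(iter(alleles)).endswith("h")


@dataclass
class Pedigree:
    """A multi-generation selfing pedigree."""

    plants: list[PlantGenotype]

    def __post_init__(self) -> None:
        self._by_id = {p.plant_id: p for p in self.plants}

    def plant(self, plant_id: str) -> PlantGenotype:
        return self._by_id[plant_id]

    def generations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.plants:
            seen.setdefault(p.generation, None)
        return list(seen)

    def generation(self, label: str) -> list[PlantGenotype]:
        return [p for p in self.plants if p.generation == label]

    def offspring_of(self, plant_id: str) -> list[PlantGenotype]:
        return [p for p in self.plants if p.parent_id == plant_id]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.plants:
            for locus, alleles in sorted(p.loci.items()):
                rows.append(
                    {
                        "plant_id": p.plant_id,
                        "parent_id": p.parent_id or "",
                        "generation": p.generation,
                        "locus": locus,
                        "allele1": alleles[0],
                        "allele2": alleles[1] if len(alleles) > 1 else alleles[0],
                        "allele_set": "/".join(alleles),
                        "transgenic": int(p.transgenic),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Pedigree":
        plants = []
        for (pid, parent, gen, tg), sub in df.groupby(
            ["plant_id", "parent_id", "generation", "transgenic"], sort=False
        ):
            loci = {
                r.locus: tuple(str(r.allele_set).split("/"))
                for r in sub.itertuples()
            }
            plants.append(
                PlantGenotype(
                    plant_id=str(pid),
                    generation=str(gen),
                    loci=loci,
                    transgenic=bool(tg),
                    parent_id=str(parent) or None,
                )
            )
        return cls(plants)

    @classmethod
    def from_csv(cls, path) -> "Pedigree":
        return cls.from_dataframe(pd.read_csv(path, keep_default_na=False))


@dataclass
class SegregationResult:
    """Pearson chi-square test of a transgenic:non-transgenic ratio."""

    n_transgenic: int
    n_nontransgenic: int
    expected_ratio: tuple[int, int]
    chi_square: float
    df: int
    p_value: float
    alpha: float
    consistent: bool

    def summary(self) -> str:
        r = self.expected_ratio
        verdict = "consistent" if self.consistent else "inconsistent"
        return (
            f"observed {self.n_transgenic}:{self.n_nontransgenic} vs expected "
            f"{r[0]}:{r[1]}  chi2={self.chi_square:.3f} (df={self.df}), "
            f"p={self.p_value:.4f} -> {verdict} at alpha={self.alpha}"
        )


def expected_segregation(n_unlinked_insertions: int) -> tuple[int, int]:
    """Transgenic:non-transgenic ratio in selfed progeny.

    A plant hemizygous at n unlinked insertion loci transmits at least
    one copy to all but (1/4)^n of its selfed offspring, giving a
    (4^n - 1):1 ratio; n = 1 is the classic 3:1.
    """
    if n_unlinked_insertions < 0:
        raise ValueError("n must be >= 0")
    if n_unlinked_insertions == 0:
        return (0, 1)
    return (4**n_unlinked_insertions - 1, 1)


def segregation_test(
    n_pos: int,
    n_neg: int,
    ratio: tuple[int, int] = (3, 1),
    alpha: float = 0.05,
) -> SegregationResult:
    """Pearson chi-square (df=1, no continuity correction) against a ratio."""
    total = n_pos + n_neg
    if total < 1:
        raise ValueError("zero total")
    frac = Fraction(ratio[0], ratio[0] + ratio[1])
    expected = [total * float(frac), total * float(1 - frac)]
    chi2, p = stats.chisquare([n_pos, n_neg], f_exp=expected)
    return SegregationResult(
        n_transgenic=n_pos,
        n_nontransgenic=n_neg,
        expected_ratio=ratio,
        chi_square=float(chi2),
        df=1,
        p_value=float(p),
        alpha=alpha,
        consistent=bool(p >= alpha),
    )


@dataclass
class InheritanceReport:
    """Per-locus classification of allele transmission in a pedigree."""

    de_novo: list[tuple[str, str, str, bool]]  # plant, locus, allele, anomalous
    lost_parental: list[tuple[str, str, str]]  # parent, locus, allele
    n_inherited: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "de_novo", "plant": p, "locus": l, "allele": a,
             "anomalous": anom}
            for p, l, a, anom in self.de_novo
        ] + [
            {"kind": "lost_parental", "plant": p, "locus": l, "allele": a,
             "anomalous": False}
            for p, l, a in self.lost_parental
        ]
        return pd.DataFrame(rows, columns=["kind", "plant", "locus", "allele",
                                           "anomalous"])


def track_alleles(pedigree: Pedigree) -> InheritanceReport:
    """Classify every transmitted allele as inherited, de novo, or lost.

    An offspring allele absent from its parent's (clone-derived) allele
    set is de novo; that is expected while the transgene (Cas9) is
    present, otherwise it is flagged anomalous.  A parental mutant
    allele found in none of the parent's offspring is lost — the
    signature of a somatic-only (non-germline) mutation in a chimeric
    parent.
    """
    if len(pedigree.generations()) < 2:
        raise ValueError("pedigree needs at least 2 generations")
    for p in pedigree.plants:
        if p.parent_id is not None and p.parent_id not in pedigree._by_id:
            raise ValueError(f"orphan node {p.plant_id}: parent {p.parent_id} unknown")

    de_novo: list[tuple[str, str, str, bool]] = []
    lost: list[tuple[str, str, str]] = []
    n_inherited = 0

    for parent in pedigree.plants:
        offspring = pedigree.offspring_of(parent.plant_id)
        if not offspring:
            continue
        for locus, parental_alleles in parent.loci.items():
            parental = set(parental_alleles)
            transmitted: set[str] = set()
            for child in offspring:
                for allele in child.loci.get(locus, ()):
                    if allele in parental:
                        transmitted.add(allele)
                        n_inherited += 1
                    else:
                        de_novo.append(
                            (child.plant_id, locus, allele, not child.transgenic)
                        )
            for allele in sorted(parental - transmitted):
                if not allele.endswith("h"):
                    lost.append((parent.plant_id, locus, allele))
    return InheritanceReport(de_novo=de_novo, lost_parental=lost,
                             n_inherited=n_inherited)


def select_candidates(
    genotypes: list[PlantGenotype],
    required_homozygous_loci: list[str],
    require_nontransgenic: bool = True,
    log: list[str] | None = None,
) -> list[PlantGenotype]:
    """Plants homozygous mutant at every required locus (and T-DNA-free).

    Returned in deterministic plant_id order.  When nothing qualifies,
    a diagnostic line is appended to ``log`` (if given).
    """
    selected = []
    for p in genotypes:
        if require_nontransgenic and p.transgenic:
            continue
        if all(
            locus in p.loci and p.is_homozygous_mutant(locus)
            for locus in required_homozygous_loci
        ):
            selected.append(p)
    selected.sort(key=lambda p: p.plant_id)
    if not selected and log is not None:
        n_tg = sum(1 for p in genotypes if p.transgenic)
        log.append(
            f"no candidate homozygous at {required_homozygous_loci} "
            f"({n_tg}/{len(genotypes)} plants still transgenic)"
        )
    return selected


def enumerate_gamete_ratio(n_loci: int) -> tuple[int, int]:
    """Brute-force transgenic:non-transgenic count over all gamete pairs.

    Exhaustive enumeration of the 4^n gamete combinations of a selfed
    plant hemizygous at n unlinked loci; cross-checks
    :func:`expected_segregation` for small n.
    """
    pos = neg = 0
    gametes = list(product([0, 1], repeat=n_loci))
    for g1 in gametes:
        for g2 in gametes:
            if any(a + b > 0 for a, b in zip(g1, g2)) if n_loci else False:
                pos += 1
            else:
                neg += 1
    return pos, neg
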