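"""Seeded synthetic data emulating a tetraploid knockout experiment.

Generates every input the pipeline consumes, with the statistical
structure typical of a polyploid CRISPR experiment in oilseed rape:

* gene families of 2-8 paralogous copies at 89-99% pairwise nucleotide
  identity, optionally carrying an identical guide target site with a
  single diagnostic SNP in one copy;
* NHEJ edit outcomes: 3-8 distinct indel alleles per chimeric T1 locus,
  drawn from a configurable insertion/deletion size spectrum and placed
  at the Cas9 cut (3 bp PAM-proximal of the PAM);
* idealised four-channel Sanger-like chromatograms (one Gaussian peak
  per base) and their mixtures;
* selfing pedigrees with Mendelian locus sampling, a single hemizygous
  T-DNA insertion segregating 3:1, configurable germline subsets for
  chimeric founders (somatic-only alleles are lost) and a per-locus
  de novo edit probability while the transgene is present;
* replicate phenotype tables with multiplicative genotype effects
  (e.g. triple-mutant phytic acid x0.65-0.73, inorganic P x3).

Every generator takes an explicit seed and is byte-reproducible; no
global random state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from polyko._seq import DNA, random_dna
from polyko.guides import GuideCandidate, locate_guide
from polyko.inheritance import Pedigree, PlantGenotype
from polyko.paralogs import GeneFamily, ParalogRecord, pairwise_identity_matrix
from polyko.traces import TraceSet

__all__ = [
    "FamilySpec",
    "PlantedSite",
    "IndelSpectrum",
    "PhenotypeEffectSpec",
    "simulate_gene_family",
    "simulate_nhej_alleles",
    "simulate_chromatogram",
    "simulate_pedigree",
    "simulate_phenotypes",
]


@dataclass
class PlantedSite:
    """A guide target site to embed identically in every family copy.

    If ``snp_paralog_index`` is set, that copy instead differs at
    exactly ``snp_position_from_pam`` (1 = PAM-proximal) — the
    one-diagnostic-SNP configuration that a family-conserved guide
    design must tolerate.
    """

    protospacer: str
    pam: str
    snp_paralog_index: int | None = None
    snp_position_from_pam: int | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be exactly 20 nt")
        if len(self.pam) != 3 or self.pam[1] != "G" or self.pam[2] != "G":
            raise ValueError("PAM must match NGG")
        if (self.snp_paralog_index is None) != (self.snp_position_from_pam is None):
            raise ValueError("snp_paralog_index and snp_position_from_pam go together")
        if self.snp_position_from_pam is not None and not (
            1 <= self.snp_position_from_pam <= 20
        ):
            raise ValueError("snp_position_from_pam must be in 1..20")

    @property
    def site(self) -> str:
        return self.protospacer + self.pam


@dataclass
class FamilySpec:
    """Parameters of one simulated paralog family."""

    ancestral_length: int = 600
    n_copies: int = 4
    target_identity_range: tuple[float, float] = (0.89, 0.99)
    site_spec: PlantedSite | None = None
    seed: int = 0
    name: str = "fam"
    subgenomes: tuple[str, ...] = ("A", "C")

    def __post_init__(self) -> None:
        lo, hi = self.target_identity_range
        if self.n_copies < 2:
            raise ValueError("n_copies must be >= 2")
        if not (0.85 <= lo <= hi <= 1.0):
            raise ValueError("identity range must satisfy 0.85 <= low <= high <= 1.0")
        if self.ancestral_length < 200:
            raise ValueError("ancestral_length must be >= 200")


def simulate_gene_family(spec: FamilySpec) -> GeneFamily:
    """Derive ``n_copies`` paralogs from one ancestor by seeded substitutions.

    Each copy mutates a disjoint set of positions, so the divergence
    between copies i and j is exactly d_i + d_j and every pairwise
    identity is guaranteed inside ``target_identity_range``.  If a site
    is planted, the protospacer+PAM is embedded identically in all
    copies except the designated SNP copy, which differs at exactly the
    requested position from the PAM.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.ancestral_length
    lo, hi = spec.target_identity_range
    ancestor = list(random_dna(L, rng))

    protected: set[int] = set()
    site_start = None
    if spec.site_spec is not None:
        site = spec.site_spec.site
        # keep generous flanks so downstream amplicon analyses have context
        site_start = int(rng.integers(60, L - len(site) - 60))
        ancestor[site_start : site_start + len(site)] = list(site)
        protected = set(range(site_start, site_start + len(site)))

    # per-copy substitution counts: identity(i,j) = 1 - (d_i + d_j)/L.
    # the diagnostic SNP adds one extra mismatch, so reserve margin for it.
    margin = 1 if (spec.site_spec and spec.site_spec.snp_paralog_index is not None) else 0
    # pairwise divergence h = d_i + d_j must satisfy identity <= hi even for a
    # co-optimal alignment that trades two substitutions for a gap pair, whose
    # measured identity is at most (L - h/2)/(L + h/2); hence h >= 2L(1-hi)/(1+hi)
    d_min = int(np.ceil(L * (1.0 - hi) / (1.0 + hi)))
    d_max = int(np.floor((L * (1.0 - lo) - margin) / 2.0))
    if d_max < d_min:
        raise ValueError("identity range unreachable at the given length")
    free = [i for i in range(L) if i not in protected]
    if spec.n_copies * d_max > len(free):
        d_max = len(free) // spec.n_copies
        if d_max < d_min:
            raise ValueError("identity range unreachable at the given length")

    counts = [int(rng.integers(d_min, d_max + 1)) for _ in range(spec.n_copies)]
    pool = list(rng.permutation(free))
    members = []
    offset = 0
    for i in range(spec.n_copies):
        seq = list(ancestor)
        for pos in pool[offset : offset + counts[i]]:
            current = seq[pos]
            seq[pos] = rng.choice([b for b in DNA if b != current])
        offset += counts[i]
        if (
            spec.site_spec is not None
            and spec.site_spec.snp_paralog_index == i
        ):
            idx = site_start + 20 - spec.site_spec.snp_position_from_pam
            current = seq[idx]
            seq[idx] = rng.choice([b for b in DNA if b != current])
        sub = spec.subgenomes[i % len(spec.subgenomes)]
        chrom = f"{sub}{i + 1:02d}"
        members.append(
            ParalogRecord(
                id=f"{spec.name}.{chrom}",
                contig=f"{spec.name}_{chrom}",
                start=0,
                end=L,
                strand="+",
                cds_sequence="".join(seq),
            )
        )

    identity = (
        pairwise_identity_matrix(members) if spec.n_copies >= 2 else np.eye(1)
    )
    fam = GeneFamily(spec.name, members, identity)
    fam.attrs["site_start"] = site_start
    fam.attrs["spec_seed"] = spec.seed
    return fam


@dataclass
class IndelSpectrum:
    """Distribution of NHEJ indel sizes (keys: +insertion / -deletion).

    The default puts 0.3 on +1 insertions and 0.7 on deletions of 1-10
    bp with geometrically decaying probability — the small-indel bias
    characteristic of NHEJ repair.
    """

    probs: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.probs:
            dele = np.array([0.5**k for k in range(10)])
            dele = 0.7 * dele / dele.sum()
            self.probs = {1: 0.3, **{-(k + 1): float(p) for k, p in enumerate(dele)}}
        if any(k == 0 for k in self.probs):
            raise ValueError("indel sizes must be nonzero")
        if any(p < 0 for p in self.probs.values()):
            raise ValueError("probabilities must be nonnegative")
        if abs(sum(self.probs.values()) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    @property
    def insertion_probs(self) -> dict[int, float]:
        return {k: p for k, p in self.probs.items() if k > 0}

    @property
    def deletion_probs(self) -> dict[int, float]:
        return {k: p for k, p in self.probs.items() if k < 0}

    def sample(self, rng: np.random.Generator) -> int:
        sizes = sorted(self.probs)
        p = np.array([self.probs[s] for s in sizes])
        return int(rng.choice(sizes, p=p))


def _apply_indel(locus_seq: str, cut: int, size: int, rng: np.random.Generator) -> str:
    """Place one indel of signed ``size`` at the cut (deletion spans it)."""
    if size > 0:
        ins = random_dna(size, rng)
        return locus_seq[:cut] + ins + locus_seq[cut:]
    k = -size
    start = max(0, cut - k // 2)
    return locus_seq[:start] + locus_seq[start + k :]


def simulate_nhej_alleles(
    locus_seq: str,
    guide: GuideCandidate,
    n_alleles: int,
    spectrum: IndelSpectrum | None = None,
    seed: int = 0,
    max_retries: int = 200,
) -> list[str]:
    """``n_alleles`` distinct edited sequences at the guide's cut site.

    Each allele differs from the locus by exactly one indel drawn from
    ``spectrum``, placed at the blunt cut 3 bp PAM-proximal of the PAM.
    Distinctness is enforced by resampling; an overly small spectrum
    raises after ``max_retries`` draws.
    """
    if not 0 <= n_alleles <= 12:
        raise ValueError("n_alleles must be in 0..12")
    if n_alleles == 0:
        return []
    spectrum = spectrum or IndelSpectrum()
    rng = np.random.default_rng(seed)
    cut, _ = locate_guide(locus_seq, guide)
    locus_seq = locus_seq.upper()

    alleles: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(alleles) < n_alleles:
        attempts += 1
        if attempts > max_retries:
            raise ValueError(
                f"spectrum too small to yield {n_alleles} distinct alleles"
            )
        size = spectrum.sample(rng)
        seq = _apply_indel(locus_seq, cut, size, rng)
        if seq not in seen and seq != locus_seq:
            seen.add(seq)
            alleles.append(seq)
    return alleles


def simulate_chromatogram(
    allele_seqs: list[str],
    weights: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    spacing: int = 10,
    peak_sd: float | None = None,
) -> TraceSet:
    """Render a mixed four-channel Sanger-like trace.

    Each allele is rendered as one Gaussian peak per base (unit
    amplitude, fixed ``spacing`` positions per base); the output is the
    weight-averaged sum plus seeded Gaussian noise, clipped at zero.
    """
    if not allele_seqs:
        raise ValueError("empty allele list")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(allele_seqs) or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative, sum to 1, one per allele")
    peak_sd = peak_sd if peak_sd is not None else spacing / 4.0

    n_pos = max(len(s) for s in allele_seqs) * spacing + spacing
    x = np.arange(n_pos)
    total = np.zeros((n_pos, 4))
    for seq, weight in zip(allele_seqs, w):
        if weight == 0:
            continue
        trace = np.zeros((n_pos, 4))
        for b, base in enumerate(seq.upper()):
            centre = b * spacing + spacing // 2
            lo = max(0, centre - 4 * int(peak_sd) - 1)
            hi = min(n_pos, centre + 4 * int(peak_sd) + 2)
            trace[lo:hi, DNA.index(base)] += np.exp(
                -0.5 * ((x[lo:hi] - centre) / peak_sd) ** 2
            )
        total += weight * trace

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        total = total + rng.normal(0.0, noise_sd, size=total.shape)
    return TraceSet(np.clip(total, 0.0, None), spacing=spacing)


def simulate_pedigree(
    founder: PlantGenotype,
    n_generations: int,
    offspring_per_plant: int,
    seed: int = 0,
    de_novo_rate: float = 0.0,
    select: "callable | None" = None,
) -> Pedigree:
    """Self a founder for ``n_generations``, Mendelian at every locus.

    Non-chimeric parents transmit each gamete allele uniformly from
    their pair.  A chimeric founder transmits from its ``germline``
    subset (somatic-only alleles are lost).  The T-DNA behaves as a
    single unlinked insertion: a hemizygous parent's selfed offspring
    are transgenic 3:1.  While the transgene is present, each wild-type
    allele drawn may be converted to a fresh de novo mutant allele with
    probability ``de_novo_rate`` (Cas9 still active).

    ``select`` optionally maps a list of offspring to the subset to
    self into the next generation (default: all of them).
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    rng = np.random.default_rng(seed)
    plants = [founder]
    current = [founder]
    gen0 = int(founder.generation[1:]) if founder.generation.startswith("T") else 1
    de_novo_counter = {locus: 0 for locus in founder.loci}

    for g in range(1, n_generations + 1):
        label = f"T{gen0 + g}"
        next_gen: list[PlantGenotype] = []
        for parent in current:
            pools = {}
            for locus, alleles in parent.loci.items():
                if parent.germline and locus in parent.germline:
                    pools[locus] = list(parent.germline[locus])
                elif len(set(alleles)) > 2:
                    # chimeric without an explicit germline: whole set
                    pools[locus] = list(alleles)
                else:
                    pools[locus] = [alleles[0], alleles[-1]]
            for k in range(offspring_per_plant):
                tdna = sum(
                    int(rng.random() < parent.tdna_count / 2.0) for _ in range(2)
                )
                loci = {}
                for locus, pool in pools.items():
                    pair = [str(rng.choice(pool)), str(rng.choice(pool))]
                    if tdna > 0 and de_novo_rate > 0:
                        for a in range(2):
                            if pair[a].endswith("h") and rng.random() < de_novo_rate:
                                de_novo_counter[locus] += 1
                                pair[a] = f"{locus}dn{de_novo_counter[locus]}"
                    loci[locus] = tuple(pair)
                next_gen.append(
                    PlantGenotype(
                        plant_id=f"{label}_{parent.plant_id}_{k:03d}",
                        generation=label,
                        loci=loci,
                        transgenic=tdna > 0,
                        tdna_count=tdna,
                        parent_id=parent.plant_id,
                    )
                )
        plants.extend(next_gen)
        current = select(next_gen) if select is not None else next_gen
        if not current:
            break
    return Pedigree(plants)


@dataclass
class PhenotypeEffectSpec:
    """Multiplicative per-genotype-class effects on trait means.

    ``control_means`` gives each trait's control mean (units per trait);
    ``effects`` maps genotype class -> trait -> multiplier (missing
    entries default to 1.0, i.e. no effect).  Replicate values are
    Normal(mean x effect, CV x mean x effect).
    """

    control_means: dict[str, float]
    effects: dict[str, dict[str, float]]
    cv: float = 0.05
    n_replicates: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.control_means.values()):
            raise ValueError("control means must be positive")
        if any(e <= 0 for eff in self.effects.values() for e in eff.values()):
            raise ValueError("effects must be positive")
        if not 0 < self.cv < 1:
            raise ValueError("CV must be in (0, 1)")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates")


def simulate_phenotypes(
    genotype_classes: list[str], spec: PhenotypeEffectSpec
) -> pd.DataFrame:
    """Long-format replicate phenotype table for the given classes.

    Columns: plant_id, line, genotype_class, trait, replicate, value.
    The first class is conventionally the control.
    """
    if len(genotype_classes) < 2:
        raise ValueError("need >= 2 genotype classes including a control")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cls in genotype_classes:
        for trait, mean in spec.control_means.items():
            effect = spec.effects.get(cls, {}).get(trait, 1.0)
            mu = mean * effect
            values = rng.normal(mu, spec.cv * mu, size=spec.n_replicates)
            for rep, v in enumerate(values, start=1):
                rows.append(
                    {
                        "plant_id": f"{cls}_{rep}",
                        "line": cls,
                        "genotype_class": cls,
                        "trait": trait,
                        "replicate": rep,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)
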