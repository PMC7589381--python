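"""End-to-end demonstration workflow on synthetic tetraploid data.

``run_demo`` recapitulates a full multi-paralog knockout campaign:
simulate two paralog families in a synthetic genome, discover the
paralogs back, design family-conserved guides, edit chimeric T1 loci,
genotype plasmid clones, decompose a mixed trace, self the founder for
three generations with selection, test transgene segregation, select
non-transgenic triple-homozygous plants (expected by T4), and run the
phenotype statistics.  Fully reproducible under one seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from polyko._seq import gc_percent, random_dna
from polyko.genotyping import assess_chimerism, call_alleles, name_alleles
from polyko.guides import design_guides, locate_guide
from polyko.inheritance import (
    Pedigree,
    PlantGenotype,
    segregation_test,
    select_candidates,
    track_alleles,
)
from polyko.io import write_fasta
from polyko.paralogs import ParalogRecord, find_paralogs, group_families
from polyko.phenostats import anova_tukey, fold_change, percent_change
from polyko.synthetic import (
    FamilySpec,
    PlantedSite,
    simulate_chromatogram,
    simulate_gene_family,
    simulate_nhej_alleles,
    simulate_pedigree,
    simulate_phenotypes,
    PhenotypeEffectSpec,
)
from polyko.traces import decompose_trace


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of the demo workflow (recorded in every output header)."""

    seed: int = 0
    outdir: str = "polyko_demo"
    ancestral_length: int = 600
    gc_min: float = 40.0
    max_mismatches: int = 1
    seed_boundary: int = 10
    offtarget_mm: int = 2
    alpha: float = 0.05
    offspring_per_plant: int = 60
    n_generations: int = 3
    de_novo_rate: float = 0.02
    n_clones: int = 40
    write_outputs: bool = True
    # phenotype effects: the two triple lines reduce phytic acid by 35.3%
    # and 27.2% and triple inorganic P; double mutants shift only slightly
    control_means: dict = field(default_factory=lambda: {
        "phytic_acid": 25.0, "inorganic_P": 1.0, "oil_percent": 45.0,
        "plant_height": 120.0, "tkw": 4.5, "root_length": 6.0,
        "hypocotyl_length": 4.0,
    })
    effects: dict = field(default_factory=lambda: {
        "triple_190665": {"phytic_acid": 0.728, "inorganic_P": 3.0},
        "triple_190666": {"phytic_acid": 0.647, "inorganic_P": 3.0},
        "double_190667": {"phytic_acid": 0.95, "inorganic_P": 1.1},
        "double_190669": {"phytic_acid": 0.95, "inorganic_P": 1.1},
    })
    cv: float = 0.05
    n_replicates: int = 5

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _pick_protospacer(rng: np.random.Generator) -> str:
    """A random 20-mer with comfortable GC content (> 45%)."""
    while True:
        proto = random_dna(20, rng)
        if gc_percent(proto) > 45:
            return proto


def _build_world(cfg: PipelineConfig):
    """Two planted families + a genome with decoy contigs."""
    rng = np.random.default_rng(cfg.seed)
    site1 = PlantedSite(
        protospacer=_pick_protospacer(rng), pam="TGG",
        snp_paralog_index=1, snp_position_from_pam=10,
    )
    site2 = PlantedSite(protospacer=_pick_protospacer(rng), pam="AGG")
    fam1 = simulate_gene_family(FamilySpec(
        ancestral_length=cfg.ancestral_length, n_copies=4,
        target_identity_range=(0.92, 0.99), site_spec=site1,
        seed=cfg.seed + 11, name="ITPK1",
    ))
    fam2 = simulate_gene_family(FamilySpec(
        ancestral_length=cfg.ancestral_length, n_copies=2,
        target_identity_range=(0.92, 0.99), site_spec=site2,
        seed=cfg.seed + 12, name="ITPK4",
    ))

    genome: dict[str, str] = {}
    flank = 300
    for fam in (fam1, fam2):
        new_members = []
        for m in fam.members:
            left = random_dna(flank, rng)
            right = random_dna(flank, rng)
            genome[m.contig] = left + m.cds_sequence + right
            new_members.append(ParalogRecord(
                id=m.id, contig=m.contig, start=flank,
                end=flank + len(m.cds_sequence), strand="+",
                cds_sequence=m.cds_sequence,
            ))
        fam.members = new_members
    for d in range(2):
        genome[f"decoy{d + 1}"] = random_dna(3000, rng)
    return fam1, fam2, genome


def run_demo(config: PipelineConfig | None = None) -> dict:
    """Run the whole synthetic knockout campaign; return the run report."""
    cfg = config or PipelineConfig()
    report: dict = {"seed": cfg.seed, "config_digest": cfg.digest(), "stages": {}}
    log: list[str] = []
    outdir = Path(cfg.outdir)
    if cfg.write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    def header(extra: str = "") -> list[str]:
        lines = [f"seed={cfg.seed}", f"config={cfg.digest()}"]
        return lines + ([extra] if extra else [])

    # --- stage 1: simulate the world and rediscover the paralogs -------
    try:
        fam1, fam2, genome = _build_world(cfg)
        discovered = {}
        for fam in (fam1, fam2):
            hits = find_paralogs(fam.members[0].cds_sequence, genome,
                                 min_identity=0.8, min_coverage=0.8)
            discovered[fam.name] = hits
            log.append(f"discovery: {fam.name}: {len(hits)} paralogs found")
        all_hits = [h for hits in discovered.values() for h in hits]
        families_found = group_families(all_hits, within_threshold=0.85)
        report["stages"]["discovery"] = {
            "n_paralogs": {k: len(v) for k, v in discovered.items()},
            "n_families": len(families_found),
            "within_identity_min": float(min(
                fam.identity_matrix[np.triu_indices(len(fam.members), 1)].min()
                for fam in (fam1, fam2)
            )),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("discovery", str(e)) from e

    # --- stage 2: guide design ----------------------------------------
    try:
        guides = {}
        for fam in (fam1, fam2):
            accepted = design_guides(
                fam, genome, gc_min=cfg.gc_min,
                max_mismatches=cfg.max_mismatches,
                seed_boundary=cfg.seed_boundary,
                offtarget_mm=cfg.offtarget_mm, log=log,
            )
            if not accepted:
                raise StageError("design", f"no guide for {fam.name}")
            guides[fam.name] = accepted[0]
        report["stages"]["design"] = {
            fam.name: {
                "protospacer": guides[fam.name].protospacer,
                "pam": guides[fam.name].pam,
                "gc_percent": round(guides[fam.name].gc_percent, 1),
                "total_mismatches": guides[fam.name].total_mismatches,
                "off_target_hits": guides[fam.name].off_target_hits,
            }
            for fam in (fam1, fam2)
        }
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001
        raise StageError("design", str(e)) from e

    # --- stage 3: T1 chimeras, clone genotyping, trace decomposition --
    # loci A, B from the first family, E, G from the second; the E-locus
    # mutations are somatic only (excluded from the germline)
    locus_map = {
        "A": (fam1, fam1.members[0]), "B": (fam1, fam1.members[1]),
        "E": (fam2, fam2.members[0]), "G": (fam2, fam2.members[1]),
    }
    try:
        rng = np.random.default_rng(cfg.seed + 31)
        founder_loci: dict[str, tuple[str, ...]] = {}
        codings: dict[str, dict] = {}
        chimerism: dict[str, dict] = {}
        clone_fastas: dict[str, str] = {}
        for locus, (fam, member) in locus_map.items():
            guide = guides[fam.name]
            n_alleles = int(rng.integers(3, 9))
            alleles = simulate_nhej_alleles(
                member.cds_sequence, guide, n_alleles,
                seed=cfg.seed + 100 + ord(locus),
            )
            # clone library: wild type plus the mutant alleles, WT-heavy
            w = np.full(len(alleles) + 1, 0.6 / len(alleles))
            w[0] = 0.4
            clone_pool = [member.cds_sequence] + alleles
            idx = rng.choice(len(clone_pool), size=cfg.n_clones, p=w)
            clones = [clone_pool[i] for i in idx]
            for ci, seq in enumerate(clones):
                clone_fastas[f"T1|{locus}|clone{ci + 1}"] = seq
            chim = assess_chimerism(clones, member.cds_sequence, guide=guide,
                                    locus_code=locus)
            calls = [
                call_alleles(a, member.cds_sequence, guide=guide, locus_code=locus)
                for a in [member.cds_sequence] + alleles
            ]
            coding = name_alleles({locus: calls})[locus]
            codings[locus] = coding
            founder_loci[locus] = tuple(c.allele_code for c in calls)
            chimerism[locus] = {
                "n_planted": n_alleles,
                "n_recovered": chim.n_mutant_alleles,
                "edited_fraction": round(chim.edited_fraction, 3),
                "chimeric": chim.chimeric,
                "saturation_warning": chim.saturation_warning,
            }
        report["stages"]["genotyping"] = chimerism

        # trace decomposition at locus A: wild type + one deletion allele
        memA = locus_map["A"][1]
        guideA = guides["ITPK1"]
        cutA, _ = locate_guide(memA.cds_sequence, guideA)
        del6 = memA.cds_sequence[: cutA - 3] + memA.cds_sequence[cutA + 3 :]
        control = simulate_chromatogram([memA.cds_sequence], [1.0],
                                        seed=cfg.seed + 41)
        mixed = simulate_chromatogram([memA.cds_sequence, del6], [0.5, 0.5],
                                      noise_sd=0.02, seed=cfg.seed + 42)
        decomp = decompose_trace(mixed, control, cut_index=cutA)
        report["stages"]["decomposition"] = {
            "r_squared": round(decomp.r_squared, 4),
            "wild_type_fraction": round(decomp.frequencies[0], 3),
            "del6_fraction": round(decomp.frequencies[-6], 3),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("genotyping", str(e)) from e

    # --- stage 4: pedigree, segregation, selection --------------------
    try:
        founder = PlantGenotype(
            plant_id="itpk_C1.1", generation="T1", loci=founder_loci,
            transgenic=True, tdna_count=1,
            germline={
                "A": (_mutant_code(codings["A"], 1), "Ah"),
                "B": (_mutant_code(codings["B"], 1), "Bh"),
                "G": (_mutant_code(codings["G"], 1), "Gh"),
                "E": ("Eh", "Eh"),  # somatic-only: no E mutation in the germline
            },
        )
        selected_loci = ["A", "B", "G"]

        def select(offspring):
            def key(p):
                n_hom = sum(p.is_homozygous_mutant(l) for l in selected_loci)
                return (-n_hom, p.tdna_count, p.plant_id)
            return sorted(offspring, key=key)[:3]

        pedigree = simulate_pedigree(
            founder, n_generations=cfg.n_generations,
            offspring_per_plant=cfg.offspring_per_plant,
            seed=cfg.seed + 51, de_novo_rate=cfg.de_novo_rate, select=select,
        )
        t2 = pedigree.generation("T2")
        seg = segregation_test(
            sum(p.transgenic for p in t2), sum(not p.transgenic for p in t2),
            ratio=(3, 1), alpha=cfg.alpha,
        )
        tracking = track_alleles(pedigree)
        final_gen = pedigree.generations()[-1]
        candidates = select_candidates(
            pedigree.generation(final_gen), selected_loci,
            require_nontransgenic=True, log=log,
        )
        e_lost = sorted({a for _, l, a in tracking.lost_parental if l == "E"})
        report["stages"]["inheritance"] = {
            "t2_segregation": seg.summary(),
            "segregation_consistent_3_1": seg.consistent,
            "final_generation": final_gen,
            "n_triple_homozygous_nontransgenic": len(candidates),
            "candidate_ids": [p.plant_id for p in candidates[:5]],
            "E_alleles_lost": e_lost,
            "n_de_novo": len(tracking.de_novo),
            "n_anomalous": sum(1 for d in tracking.de_novo if d[3]),
        }
        if not candidates:
            log.append("selection: no triple-homozygous non-transgenic plant found")
    except Exception as e:  # noqa: BLE001
        raise StageError("inheritance", str(e)) from e

    # --- stage 5: phenotype statistics --------------------------------
    try:
        classes = ["control_190668", "double_190667", "double_190669",
                   "triple_190665", "triple_190666"]
        pheno_spec = PhenotypeEffectSpec(
            control_means=dict(cfg.control_means), effects=dict(cfg.effects),
            cv=cfg.cv, n_replicates=cfg.n_replicates, seed=cfg.seed + 61,
        )
        table = simulate_phenotypes(classes, pheno_spec)
        pa = anova_tukey(table, "phytic_acid", alpha=cfg.alpha)
        pi = anova_tukey(table, "inorganic_P", alpha=cfg.alpha)
        control_pa = float(table.query(
            "line == 'control_190668' and trait == 'phytic_acid'")["value"].mean())
        control_pi = float(table.query(
            "line == 'control_190668' and trait == 'inorganic_P'")["value"].mean())
        reductions = {}
        folds = {}
        for cls in ("triple_190665", "triple_190666"):
            m_pa = float(table.query(
                f"line == '{cls}' and trait == 'phytic_acid'")["value"].mean())
            m_pi = float(table.query(
                f"line == '{cls}' and trait == 'inorganic_P'")["value"].mean())
            reductions[cls] = round(-percent_change(m_pa, control_pa), 1)
            folds[cls] = round(fold_change(m_pi, control_pi), 2)
        report["stages"]["phenotypes"] = {
            "pa_anova_p": float(pa.p_value),
            "pa_letters": pa.letters,
            "pi_letters": pi.letters,
            "pa_reduction_percent": reductions,
            "pi_fold_change": folds,
            "triples_differ_from_control_pa": not (
                set(pa.letters["triple_190665"]) & set(pa.letters["control_190668"])
                or set(pa.letters["triple_190666"]) & set(pa.letters["control_190668"])
            ),
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("phenotypes", str(e)) from e

    report["log"] = log

    if cfg.write_outputs:
        write_fasta(genome, outdir / "genome.fasta")
        write_fasta({m.id: m.cds_sequence for fam in (fam1, fam2)
                     for m in fam.members}, outdir / "families.fasta")
        write_fasta(clone_fastas, outdir / "t1_clones.fasta")
        control.to_tsv(outdir / "trace_control.tsv")
        mixed.to_tsv(outdir / "trace_mixed.tsv")
        decomp.to_frame().to_csv(outdir / "decomposition.tsv", sep="\t", index=False)
        pedigree.to_csv(outdir / "pedigree.csv")
        table.to_csv(outdir / "phenotypes.csv", index=False)
        (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                       sort_keys=True))
        (outdir / "report.txt").write_text(
            "\n".join([f"# seed={cfg.seed} config={cfg.digest()}", "", pa.summary(),
                       "", pi.summary(), "", seg.summary(), ""] + log) + "\n"
        )
    return report


def _mutant_code(coding: dict, number: int) -> str:
    """The allele code of the ``number``-th observed mutant in a coding map."""
    for events, code in coding.items():
        if events and code[1:] == str(number):
            return code
    raise KeyError(number)
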