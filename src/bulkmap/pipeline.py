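"""End-to-end orchestration: simulate -> segregate -> bsa -> linkage ->
finemap -> haplotype, with per-stage outputs, logging and seeding."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import candgene, io, simpop
from .bsaindex import call_candidate_regions, delta_profile
from .finemap import refine_interval, screen_recombinants
from .intervals import GenomicInterval
from .linkage import GenotypeMatrix, trait_map
from .segregation import chi_square_gof

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Failure inside a named pipeline stage."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage '{name}' failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return out
        return wrapper
    return deco


def _pick_marker_positions(genome, causal_pos, n_markers, span_bp):
    """SNP positions nearest to an even grid across causal_pos +/- span/2."""
    lo = max(1, causal_pos - span_bp // 2)
    hi = min(genome.length_bp, causal_pos + span_bp // 2)
    targets = np.linspace(lo, hi, n_markers)
    chosen = []
    for t in targets:
        i = int(np.argmin(np.abs(genome.snp_positions - t)))
        p = int(genome.snp_positions[i])
        if p not in chosen:
            chosen.append(p)
    return sorted(chosen)


def run_pipeline(config: io.RunConfig) -> dict:
    """Run every stage of the demo pipeline; returns the report bundle.

    All outputs (TSV/VCF/BED/JSON) land in ``config.out_dir``; reruns
    with the same seed are byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # out_dir is excluded so reruns into different directories stay
    # byte-identical
    params = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    seeds = np.random.SeedSequence(config.seed).spawn(6)
    report: dict = {"seed": config.seed, "config_hash": io.params_hash(params)}

    # ---- simulate ---------------------------------------------------------
    @_stage("simulate")
    def _simulate():
        rng = np.random.default_rng(seeds[0])
        genome = simpop.random_genome(
            n_snps=config.n_snps,
            length_bp=config.length_bp,
            cm_per_mb=config.cm_per_mb,
            chrom_name=config.chrom_name,
            rng=rng,
            include_positions=(config.causal_pos,),
        )
        locus = simpop.CausalLocus(
            position_bp=config.causal_pos,
            dominant_parent="P2",
            dominant_phenotype=config.dominant_phenotype,
            recessive_phenotype=config.recessive_phenotype,
        )
        f2_bsa = simpop.make_f2(config.n_f2_bsa, genome, locus, rng, "BSA")
        pools = simpop.make_pools(
            f2_bsa,
            simpop.PoolSpec(config.pool_size, config.mean_depth,
                            config.recessive_phenotype),
            simpop.PoolSpec(config.pool_size, config.mean_depth,
                            config.dominant_phenotype),
            genome,
            rng,
        )
        f2_link = simpop.make_f2(config.n_f2_linkage, genome, locus, rng, "LNK")
        marker_pos = _pick_marker_positions(
            genome, config.causal_pos, config.n_linkage_markers,
            config.linkage_span_bp,
        )
        names = [f"SC_{i + 1}" for i in range(len(marker_pos))]
        frame = simpop.genotype_matrix_frame(
            f2_link, genome, marker_pos, names, trait_locus=locus
        )
        matrix = GenotypeMatrix(
            data=frame,
            positions={**dict(zip(names, marker_pos)), "trait": None},
            codings={**{n: "codominant" for n in names}, "trait": "dominant"},
        )
        io.write_pooled_tsv(pools, out_dir / "pooled_variants.tsv", params,
                            config.seed)
        io.write_pooled_vcf(pools, out_dir / "pooled_variants.vcf",
                            chrom_lengths={config.chrom_name: config.length_bp})
        io.write_genotype_matrix(matrix, out_dir / "genotype_matrix.tsv",
                                 params, config.seed)
        return genome, locus, f2_bsa, f2_link, pools, matrix, marker_pos, names

    genome, locus, f2_bsa, f2_link, pools, matrix, marker_pos, names = _simulate()

    # ---- segregation ------------------------------------------------------
    @_stage("segregate")
    def _segregate():
        results = {}
        for label, plants in (("bsa_f2", f2_bsa), ("linkage_f2", f2_link)):
            n_dom = sum(
                p.phenotype == config.dominant_phenotype for p in plants
            )
            res = chi_square_gof([n_dom, len(plants) - n_dom], [3, 1])
            results[label] = res.to_dict()
        pd.DataFrame(results).T.to_csv(out_dir / "segregation.tsv", sep="\t")
        return results

    report["segregation"] = _segregate()

    # ---- bsa --------------------------------------------------------------
    @_stage("bsa")
    def _bsa():
        rng = np.random.default_rng(seeds[1])
        snps, windows, counts = delta_profile(
            pools,
            pool_sizes=(config.pool_size, config.pool_size),
            chrom_lengths={config.chrom_name: config.length_bp},
            window_bp=config.window_bp,
            step_bp=config.step_bp,
            min_depth=config.min_depth,
            low_cut=config.low_cut,
            high_cut=config.high_cut,
            filter_mode=config.filter_mode,
            n_reps=config.n_boot_reps,
            window_ci_method=config.window_ci_method,
            rng=rng,
        )
        regions = call_candidate_regions(windows, level=config.call_level)
        io._write_table(snps, out_dir / "snp_index.tsv", params, config.seed)
        io._write_table(windows, out_dir / "windows.tsv", params, config.seed)
        io.write_bed(regions, out_dir / "candidate_regions.bed")
        return counts, regions

    filter_counts, regions = _bsa()
    report["bsa"] = {
        "filter_counts": filter_counts,
        "regions": [
            {"chrom": r.chrom, "start": r.start, "end": r.end,
             "length_mb": r.length_mb(), "sign": r.sign}
            for r in regions
        ],
    }

    # ---- linkage ----------------------------------------------------------
    @_stage("linkage")
    def _linkage():
        table = trait_map(matrix, "trait")
        io._write_table(table, out_dir / "trait_map.tsv", params, config.seed)
        coseg = table.index[table["cosegregating"]].tolist()
        if coseg:
            i0, i1 = min(coseg), max(coseg)
        else:
            i0 = i1 = int(table["cm_to_trait"].idxmin())
        left_i = max(i0 - 1, 0)
        right_i = min(i1 + 1, len(table) - 1)
        flank_left = table.at[left_i, "marker"]
        flank_right = table.at[right_i, "marker"]
        interval = GenomicInterval(
            config.chrom_name,
            int(table.at[left_i, "pos_bp"]),
            int(table.at[right_i, "pos_bp"]),
        )
        return table, flank_left, flank_right, interval

    map_table, flank_left, flank_right, link_interval = _linkage()
    report["linkage"] = {
        "n_markers": int(len(map_table)),
        "cosegregating": map_table.loc[
            map_table["cosegregating"], "marker"
        ].tolist(),
        "flanks": [flank_left, flank_right],
        "interval": {"start": link_interval.start, "end": link_interval.end,
                     "length_kb": link_interval.length_kb()},
    }

    # ---- finemap ----------------------------------------------------------
    @_stage("finemap")
    def _finemap():
        rng = np.random.default_rng(seeds[2])
        lpos = matrix.positions[flank_left]
        rpos = matrix.positions[flank_right]
        f23 = simpop.make_f23_screen(
            f2_link, config.n_f23, genome, locus, lpos, rpos, rng
        )
        inner = [
            (n, p) for n, p in zip(names, marker_pos) if lpos <= p <= rpos
        ]
        frame = simpop.genotype_matrix_frame(
            f23, genome, [p for _, p in inner], [n for n, _ in inner]
        )
        f23_matrix = GenotypeMatrix(
            data=frame,
            positions=dict(inner),
            codings={n: "codominant" for n, _ in inner},
        )
        phenos = {p.id: p.phenotype for p in f23}
        recs = screen_recombinants(f23_matrix, flank_left, flank_right, phenos)
        refined = refine_interval(
            recs,
            [p for _, p in inner],
            link_interval,
            dominant_hom="B",
            dominant_phenotype=config.dominant_phenotype,
        )
        rec_table = pd.DataFrame(
            [
                {"plant": r.id, "phenotype": r.phenotype,
                 **dict(zip([n for n, _ in inner], r.genotypes))}
                for r in recs
            ]
        )
        io._write_table(rec_table, out_dir / "recombinants.tsv", params,
                        config.seed)
        io.write_bed([refined], out_dir / "refined_interval.bed")
        return recs, refined

    recombinants, refined = _finemap()
    report["finemap"] = {
        "n_recombinants": len(recombinants),
        "interval": {"start": refined.start, "end": refined.end,
                     "length_kb": refined.length_kb()},
        "contains_causal": refined.contains(config.causal_pos),
    }

    # ---- haplotype --------------------------------------------------------
    @_stage("haplotype")
    def _haplotype():
        model, variants = candgene.example_gene_model()
        effects = [candgene.annotate_variant(model, v) for v in variants]
        low = [v.ref_base for v in variants]
        high = [v.alt_base for v in variants]
        het = [f"{a}/{b}" for a, b in zip(low, high)]
        calls = pd.DataFrame(
            [low, low, high, high, het],
            index=pd.Index(["P1_a", "P1_b", "P2_a", "P2_b", "F1"],
                           name="sample"),
            columns=[v.name for v in variants],
        )
        phen = {
            "P1_a": config.recessive_phenotype,
            "P1_b": config.recessive_phenotype,
            "P2_a": config.dominant_phenotype,
            "P2_b": config.dominant_phenotype,
            "F1": config.dominant_phenotype,
        }
        table, concordance = candgene.classify_haplotypes(calls, phen)
        effect_df = pd.DataFrame([e.__dict__ for e in effects])
        io._write_table(effect_df, out_dir / "variant_effects.tsv", params,
                        config.seed)
        io._write_table(table.reset_index(), out_dir / "haplotypes.tsv",
                        params, config.seed)
        return effects, concordance

    effects, concordance = _haplotype()
    report["haplotype"] = {
        "effects": [
            {"variant": e.variant, "synonymous": e.synonymous,
             "aa_change": f"{e.ref_aa}{e.codon_index}{e.alt_aa}"}
            for e in effects
        ],
        "concordance": concordance,
    }

    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
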