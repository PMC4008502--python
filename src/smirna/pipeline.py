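"""End-to-end orchestration of the simulate-then-analyze pipeline.

``run_pipeline`` drives every stage from a single validated config and
a single seed: reference/library simulation, read cleaning and tag
collapsing, priority annotation, known-miRNA quantification,
differential expression, novel-miRNA discovery, and target prediction.
All tables are written as TSV (plus FASTA/FASTQ/dot-bracket files) into
the run directory, and a machine-readable RunReport records the
stage-by-stage read accounting.  Outputs contain no timestamps, so two
runs with the same config are byte-identical.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__, annotate, diffexpr, hairpin, preprocess, simulate
from .annotate import NamedSeq
from .config import validate_config
from .targets import RULE_NAMES, predict_targets

__all__ = ["RunReport", "run_pipeline"]


@dataclass
class RunReport:
    """Stage-by-stage accounting of one pipeline run."""

    seed: int
    config: dict[str, Any]
    version: str = __version__
    counts: dict[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "counts": self.counts,
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
        )


def _log(msg: str, t0: float) -> None:
    print(f"[smirna +{time.perf_counter() - t0:7.2f}s] {msg}", file=sys.stderr)


def run_pipeline(cfg: dict[str, Any], outdir: str | Path) -> RunReport:
    """Run every stage on a simulated two-condition experiment.

    The config must be complete (see ``smirna.config``); it is
    re-validated here and a configuration error aborts before any
    computation.  Returns the RunReport (also written to report.json).
    """
    errors = validate_config(cfg)
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    t0 = time.perf_counter()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    report = RunReport(seed=seed, config=cfg)
    sim = cfg["simulate"]

    # --- simulate -----------------------------------------------------
    bundle = simulate.generate_reference_bundle(
        sim["n_mirnas"], sim["n_decoys"], sim["n_novel"], seed
    )
    abund = simulate.default_abundances(
        bundle,
        seed,
        dominant_share=sim["dominant_share"],
        decoy_fraction=sim["decoy_fraction"],
        novel_fraction=sim["novel_fraction"],
    )
    de_spec = {str(k): float(v) for k, v in (sim["de_spec"] or {}).items()}
    missing = set(de_spec) - set(abund)
    if missing:
        raise ValueError(f"de_spec names not in the simulated bundle: {sorted(missing)}")
    reads1, reads2, truth = simulate.make_condition_pair(
        bundle,
        abund,
        de_spec,
        tuple(sim["depths"]),
        sim["error_rate"],
        sim["adaptor3"],
        seed,
    )
    with open(out / "cond1.fastq", "w") as fh:
        simulate.write_fastq(reads1, fh)
    with open(out / "cond2.fastq", "w") as fh:
        simulate.write_fastq(reads2, fh)
    with open(out / "references_matures.fa", "w") as fh:
        simulate.write_fasta(sorted(bundle.matures.items()), fh)
    with open(out / "references_genome.fa", "w") as fh:
        simulate.write_fasta(sorted(bundle.genome.items()), fh)
    truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)
    report.counts["raw_reads"] = [len(reads1), len(reads2)]
    _log("simulated libraries", t0)

    # --- preprocess ---------------------------------------------------
    pre = cfg["preprocess"]
    tag_sets = []
    stats_rows = []
    for lib_idx, reads in enumerate((reads1, reads2), start=1):
        clean, stats = preprocess.filter_reads(
            ((r.read_id, r.sequence, r.quality) for r in reads),
            sim["adaptor3"],
            pre["min_len"],
            pre["max_len"],
            pre["min_mean_quality"],
            pre["min_overlap"],
        )
        tags = preprocess.collapse(clean)
        tag_sets.append((tags, stats))
        with open(out / f"cond{lib_idx}.tags.fa", "w") as fh:
            preprocess.write_tags_fasta(tags, fh)
        stats_rows.append(
            {
                "library": f"cond{lib_idx}",
                "raw_reads": stats.raw_reads,
                "discarded_quality": stats.discarded_quality,
                "discarded_adaptor": stats.discarded_adaptor,
                "discarded_short": stats.discarded_short,
                "clean_reads": stats.clean_reads,
            }
        )
        dist = preprocess.length_distribution(tags)
        pd.DataFrame(
            [
                {"length": n, "reads": rc, "unique_tags": uc}
                for n, (rc, uc) in dist.items()
            ]
        ).to_csv(out / f"cond{lib_idx}.lengths.tsv", sep="\t", index=False)
    pd.DataFrame(stats_rows).to_csv(out / "clean_stats.tsv", sep="\t", index=False)
    report.counts["clean_reads"] = [s.clean_reads for _, s in tag_sets]
    report.counts["unique_tags"] = [len(t) for t, _ in tag_sets]
    _log("preprocessed reads", t0)

    # --- annotate & quantify ------------------------------------------
    ann = cfg["annotate"]
    references: dict[str, list[NamedSeq]] = bundle.decoy_refs_by_class()
    references["miRNA"] = bundle.mature_refs()
    references["genome"] = [NamedSeq(n, s) for n, s in bundle.genome.items()]

    class_tables = []
    mirna_counts = []
    genome_only_tags = []
    for lib_idx, (tags, _stats) in enumerate(tag_sets, start=1):
        classes: dict[str, list[preprocess.UniqueTag]] = {}
        for tag in tags:
            cls = annotate.classify(
                tag.sequence, references, ann["max_mismatch"], ann["isomir"]
            )
            classes.setdefault(cls, []).append(tag)
        for cls in list(annotate.CLASS_PRIORITY) + ["unannotated"]:
            cls_tags = classes.get(cls, [])
            class_tables.append(
                {
                    "library": f"cond{lib_idx}",
                    "class": cls,
                    "reads": sum(t.count for t in cls_tags),
                    "unique_tags": len(cls_tags),
                }
            )
        counts = annotate.quantify_mirnas(
            classes.get("miRNA", []),
            references["miRNA"],
            ann["max_mismatch"],
            ann["isomir"],
        )
        mirna_counts.append(counts)
        genome_only_tags.append(classes.get("genome", []))
    pd.DataFrame(class_tables).to_csv(out / "class_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "name": name,
                "count_cond1": mirna_counts[0].get(name, 0),
                "count_cond2": mirna_counts[1].get(name, 0),
            }
            for name in sorted(bundle.matures)
        ]
    ).to_csv(out / "mirna_counts.tsv", sep="\t", index=False)
    top = annotate.top_k_report(mirna_counts[0], k=10)
    pd.DataFrame(top, columns=["name", "count", "percent"]).to_csv(
        out / "top10_cond1.tsv", sep="\t", index=False
    )
    report.counts["mirna_mapped_reads"] = [
        sum(c.values()) for c in mirna_counts
    ]
    _log("annotated and quantified tags", t0)

    # --- differential expression --------------------------------------
    de_cfg = cfg["diffexpr"]
    # condition 2 is the treatment (HFD analogue): x = cond2, y = cond1
    N1_treat = tag_sets[1][1].clean_reads
    N2_ctrl = tag_sets[0][1].clean_reads
    records = [
        diffexpr.ExpressionRecord(
            name=name,
            count_hfd=mirna_counts[1].get(name, 0),
            count_nfd=mirna_counts[0].get(name, 0),
            norm_hfd=diffexpr.normalize(mirna_counts[1].get(name, 0), N1_treat),
            norm_nfd=diffexpr.normalize(mirna_counts[0].get(name, 0), N2_ctrl),
        )
        for name in sorted(bundle.matures)
    ]
    de_results = diffexpr.de_table(
        records,
        N1_treat,
        N2_ctrl,
        de_cfg["alpha"],
        de_cfg["min_abs_log2fc"],
        de_cfg["min_total_count"],
        pvalue_method=de_cfg["pvalue_method"],
    )
    de_frame = diffexpr.de_results_frame(de_results)
    de_frame.to_csv(out / "de_table.tsv", sep="\t", index=False)
    tested = [
        r
        for r in de_results
        if not (r.excluded_low_expression or r.excluded_low_depth)
    ]
    significant = [r for r in de_results if r.significant]
    report.counts["de_tested"] = len(tested)
    report.counts["de_significant"] = len(significant)
    _log("differential expression", t0)

    # --- novel miRNA discovery ----------------------------------------
    hp = cfg["hairpin"]
    thresholds = hairpin.HairpinThresholds(
        tag_len_min=hp["tag_len_min"],
        tag_len_max=hp["tag_len_max"],
        mature_len_min=hp["mature_len_min"],
        mature_len_max=hp["mature_len_max"],
        min_cut_depth=hp["min_cut_depth"],
        max_copy_number=hp["max_copy_number"],
        max_mfe=hp["max_mfe"],
        max_spacing=hp["max_spacing"],
        min_duplex_pairs=hp["min_duplex_pairs"],
        max_bulge=hp["max_bulge"],
        max_asymmetry=hp["max_asymmetry"],
        flank=hp["flank"],
    )
    # pool genome-only tags across libraries (summing counts per sequence)
    pooled: dict[str, int] = {}
    for tags in genome_only_tags:
        for tag in tags:
            pooled[tag.sequence] = pooled.get(tag.sequence, 0) + tag.count
    pooled_tags = [preprocess.UniqueTag(s, c) for s, c in pooled.items()]
    novels = hairpin.discover_novel(
        pooled_tags, bundle.genome, hp["min_reads"], thresholds
    )
    novel_rows = []
    with open(out / "novel_precursors.fa", "w") as fa, open(
        out / "novel_structures.txt", "w"
    ) as st:
        for i, cand in enumerate(novels, start=1):
            name = f"candidate-{i}"
            fa.write(f">{name}\n{cand.fold_result.sequence}\n")
            st.write(
                f">{name} {cand.window.genome_name}:{cand.window.start}-"
                f"{cand.window.end}({cand.window.strand}) "
                f"mfe={cand.fold_result.mfe:.2f}\n"
                f"{cand.fold_result.sequence}\n{cand.fold_result.structure}\n"
            )
            row = {
                "name": name,
                "genome": cand.window.genome_name,
                "start": cand.window.start,
                "end": cand.window.end,
                "strand": cand.window.strand,
                "mfe": cand.fold_result.mfe,
                "passes": cand.passes,
            }
            row.update(
                dict(zip(hairpin.CRITERION_NAMES, (bool(v) for v in cand.verdicts)))
            )
            novel_rows.append(row)
    pd.DataFrame(
        novel_rows,
        columns=["name", "genome", "start", "end", "strand", "mfe", "passes"]
        + list(hairpin.CRITERION_NAMES),
    ).to_csv(out / "novel_candidates.tsv", sep="\t", index=False)
    report.counts["genome_only_tags"] = len(pooled_tags)
    report.counts["novel_passing"] = len(novels)
    _log("novel miRNA discovery", t0)

    # --- target prediction --------------------------------------------
    tg = cfg["targets"]
    de_names = [r.name for r in significant]
    query = {n: bundle.matures[n] for n in de_names if n in bundle.matures}
    sites = predict_targets(
        query,
        bundle.utrs,
        max_weighted_mismatches=tg["max_weighted_mismatches"],
        max_weighted_mismatches_1_12=tg["max_weighted_mismatches_1_12"],
        min_mfe_ratio=tg["min_mfe_ratio"],
    )
    site_rows = []
    for s in sites:
        row = {
            "utr": s.utr_name,
            "start": s.start,
            "end": s.end,
            "mirna": s.mirna_name,
            "seed_class": s.seed_class,
            "weighted_mismatches": s.weighted_mismatches,
            "mfe": s.duplex.mfe,
            "mfe_ratio": s.duplex.mfe / s.duplex.perfect_mfe
            if s.duplex.perfect_mfe < 0
            else 0.0,
            "predicted": s.predicted,
        }
        row.update(dict(zip(RULE_NAMES, (bool(v) for v in s.rule_verdicts))))
        site_rows.append(row)
    pd.DataFrame(
        site_rows,
        columns=["utr", "start", "end", "mirna", "seed_class",
                 "weighted_mismatches", "mfe", "mfe_ratio", "predicted"]
        + list(RULE_NAMES),
    ).to_csv(out / "target_sites.tsv", sep="\t", index=False)
    report.counts["target_sites_scanned"] = len(sites)
    report.counts["target_sites_predicted"] = sum(1 for s in sites if s.predicted)
    _log("target prediction", t0)

    # --- qPCR (optional) ----------------------------------------------
    qp_path = cfg["qpcr"].get("path")
    if qp_path:
        qp = pd.read_csv(qp_path, sep="\t")
        recs = [
            diffexpr.QpcrRecord(
                str(r["sample"]), str(r["group"]),
                float(r["ct_target"]), float(r["ct_reference"]),
            )
            for _, r in qp.iterrows()
        ]
        comparison = diffexpr.compare_ct_groups(recs)
        pd.DataFrame(
            [
                {
                    "ddct": comparison.ddct,
                    "fold": comparison.fold,
                    "t_statistic": comparison.t_statistic,
                    "p_value": comparison.p_value,
                    "n_nfd": comparison.n_nfd,
                    "n_hfd": comparison.n_hfd,
                }
            ]
        ).to_csv(out / "qpcr_comparison.tsv", sep="\t", index=False)

    (out / "report.json").write_text(report.to_json())
    _log("done", t0)
    return report
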