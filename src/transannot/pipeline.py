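"""End-to-end orchestration: simulate → filter → stats → annotate → compare.

The pipeline consumes contig FASTA directly (de novo assembly is
delegated to external tools and, in simulated runs, the generator's
transcripts stand in for assembled contigs).  Every stage writes its
outputs to disk and the final run report is recomputable from those
files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .aligner import align_local_nt
from .annotation_compare import (
    ComparisonSummary,
    ProteinSetEntry,
    compare_to_reference,
    filter_by_symbol,
    missing_genes,
    read_protein_set,
    single_isoform_overlap,
)
from .cds_annotator import (
    AnnotationSummary,
    annotate_transcripts,
    write_annotations,
)
from .read_filter import FilterPolicy, FilterReport, filter_pairs, write_filtered_fastq
from .seq_core import contig_stats, read_fasta, read_fastq_pairs
from .synthetic_data import SimConfig, TruthManifest, simulate_dataset

logger = logging.getLogger(__name__)

_SIM_KEYS = {f.name for f in dataclasses.fields(SimConfig)}

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "out_dir": "transannot_out",
    "sample": "synthetic",
    "simulate": True,
    # non-simulated inputs
    "transcripts": None,
    "orthologs": None,
    "reads_r1": None,
    "reads_r2": None,
    "setb_fasta": None,
    "setb_meta": None,
    "single_isoform": None,
    # read filter
    "min_len": 100,
    "max_len": 102,
    "drop_unaligned": True,
    # annotation thresholds
    "min_identity": 85.0,
    "max_length_diff": 10,
    # aligner scoring
    "match": 2,
    "mismatch": -3,
    "gap_open_nt": -5,
    "gap_extend_nt": -2,
    "max_targets": 1,
}


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration."""

    values: dict[str, Any]
    sim: SimConfig

    def __getattr__(self, name: str) -> Any:
        try:
            return self.values[name]
        except KeyError as exc:  # pragma: no cover - attribute plumbing
            raise AttributeError(name) from exc


def _coerce(key: str, value: Any, default: Any) -> Any:
    if value is None or default is None:
        return value
    if isinstance(default, bool):
        if not isinstance(value, bool):
            raise ValueError(f"config key {key!r}: expected a boolean, got {value!r}")
        return value
    if isinstance(default, int) and not isinstance(value, bool):
        if isinstance(value, float) and not value.is_integer():
            raise ValueError(f"config key {key!r}: expected an integer, got {value!r}")
        try:
            return int(value)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"config key {key!r}: expected an integer, got {value!r}"
            ) from exc
    if isinstance(default, float):
        try:
            return float(value)
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"config key {key!r}: expected a number, got {value!r}"
            ) from exc
    return value


def build_config(overrides: dict[str, Any] | None = None) -> PipelineConfig:
    """Apply defaults and validate a flat key→value configuration."""
    overrides = dict(overrides or {})
    values = dict(_DEFAULTS)
    sim_kwargs: dict[str, Any] = {}
    sim_defaults = SimConfig()
    for key, value in overrides.items():
        if key in _DEFAULTS:
            values[key] = _coerce(key, value, _DEFAULTS[key])
        elif key in _SIM_KEYS:
            default = getattr(sim_defaults, key)
            if isinstance(default, tuple):
                if not (isinstance(value, (list, tuple)) and len(value) == 2):
                    raise ValueError(f"config key {key!r}: expected a 2-element range")
                sim_kwargs[key] = (int(value[0]), int(value[1]))
            else:
                sim_kwargs[key] = _coerce(key, value, default)
        else:
            raise ValueError(f"unknown config key {key!r}")
    if values["min_len"] > values["max_len"]:
        raise ValueError(
            f"min_len {values['min_len']} > max_len {values['max_len']}"
        )
    if not 0 <= values["min_identity"] <= 100:
        raise ValueError("min_identity must be in [0, 100]")
    if values["max_length_diff"] < 0:
        raise ValueError("max_length_diff must be >= 0")
    sim_kwargs.setdefault("seed", values["seed"])
    sim = SimConfig(**sim_kwargs)
    if not values["simulate"]:
        for key in ("transcripts", "orthologs"):
            if not values[key]:
                raise ValueError(f"config key {key!r} required when simulate is false")
            if not Path(values[key]).exists():
                raise ValueError(f"input path does not exist: {values[key]}")
    return PipelineConfig(values=values, sim=sim)


def validate_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return build_config(raw)


@dataclass
class RunReport:
    """Numbers of a completed run; every value is recomputable from the
    stage outputs on disk."""

    sample: str
    filter_report: FilterReport | None
    contig_stats_row: dict[str, Any]
    annotation_summary: AnnotationSummary
    comparison: dict[str, Any] = field(default_factory=dict)
    truth_scores: dict[str, float] = field(default_factory=dict)
    config_echo: str = ""

    def to_markdown(self) -> str:
        lines = [f"# transannot run report — sample {self.sample}", ""]
        cs = self.contig_stats_row
        lines += [
            "## Contig statistics",
            "",
            "| sample | n_contigs | N50 | mean length | n unique full-length CDS (proteins / genes) |",
            "|---|---|---|---|---|",
            f"| {self.sample} | {cs['n_contigs']} | {cs['n50']} | "
            f"{round(cs['mean_length'])} | {self.annotation_summary.n_unique_proteins} / "
            f"{self.annotation_summary.n_unique_genes} |",
            "",
        ]
        if self.filter_report is not None:
            fr = self.filter_report
            lines += [
                "## Read filtering",
                "",
                f"- pairs in: {fr.n_pairs_in}; kept: {fr.n_pairs_kept}",
                f"- reads removed: {fr.n_removed_length} (length), "
                f"{fr.n_removed_unaligned} (unaligned), {fr.n_removed_mate} (mate)",
                "",
            ]
        s = self.annotation_summary
        lines += [
            "## Annotation",
            "",
            f"- transcripts: {s.n_transcripts}; annotated with full-length CDS: {s.n_annotated}",
            f"- unique proteins: {s.n_unique_proteins}; unique genes: {s.n_unique_genes}",
            f"- rejections: "
            + (", ".join(f"{k}={v}" for k, v in s.rejects_by_reason.items()) or "none"),
            "",
        ]
        if self.comparison:
            lines += [
                "## Comparison with the second annotation set",
                "",
                "| sequence source | mean % identity | mean % similarity | mean gaps |",
                "|---|---|---|---|",
            ]
            for name, summ in self.comparison.items():
                if not isinstance(summ, ComparisonSummary):
                    continue
                lines.append(
                    f"| {name} | {summ.mean_pct_identity:.2f} | "
                    f"{summ.mean_pct_similarity:.2f} | {summ.mean_gaps:.2f} |"
                )
            lines.append("")
            if "missing_in_b" in self.comparison:
                lines.append(
                    f"- genes in assembled set with no match in set B: "
                    f"{len(self.comparison['missing_in_b'])}"
                )
            if "missing_in_a" in self.comparison:
                lines.append(
                    f"- genes in set B with no match in assembled set: "
                    f"{len(self.comparison['missing_in_a'])}"
                )
            if "single_isoform_genes" in self.comparison:
                lines.append(
                    f"- single-isoform overlap genes: "
                    f"{len(self.comparison['single_isoform_genes'])}"
                )
            lines.append("")
        if self.truth_scores:
            lines += ["## Truth-based scores", ""]
            for k, v in self.truth_scores.items():
                lines.append(f"- {k}: {v:.4f}")
            lines.append("")
        lines += ["## Configuration", "", "```yaml", self.config_echo.rstrip(), "```", ""]
        return "\n".join(lines)


def _score_vs_truth(annotations, manifest: TruthManifest) -> dict[str, float]:
    """Precision/recall of accepted calls against the ground truth, plus
    the fraction of true calls with exactly recovered CDS coordinates."""
    truth_by_id = {s.id: s for s in manifest.sequences}
    positives = {s.id for s in manifest.coding_full_length()}
    accepted = {a.transcript_id: a for a in annotations if a.status == "accepted"}
    tp = {tid for tid in accepted if tid in positives}
    fp = set(accepted) - tp
    precision = len(tp) / len(accepted) if accepted else float("nan")
    recall = len(tp) / len(positives) if positives else float("nan")
    exact = 0
    for tid in tp:
        a, t = accepted[tid], truth_by_id[tid]
        if (a.cds_start, a.cds_end, a.strand) == (t.cds_start, t.cds_end, t.strand):
            exact += 1
    exact_frac = exact / len(tp) if tp else float("nan")
    return {
        "precision": precision,
        "recall": recall,
        "exact_cds_fraction": exact_frac,
    }


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages in order, writing intermediates under out_dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scoring = {
        "match": config.match,
        "mismatch": config.mismatch,
        "gap_open": config.gap_open_nt,
        "gap_extend": config.gap_extend_nt,
    }

    def _seeded_read_hits(pairs, reference):
        """Best nt hit per read, prescreened by shared words.

        Exact Smith–Waterman against every contig for every read is
        wasteful; like BLAST's word seeding, a read is only aligned against
        contigs sharing at least one exact 16-mer with either read strand.
        Reads seeding nowhere are reported as unaligned — the behaviour of
        a seeded search.
        """
        k = 16
        index: dict[str, set[int]] = {}
        for i, ref in enumerate(reference):
            seq = ref.seq
            for j in range(0, len(seq) - k + 1):
                index.setdefault(seq[j : j + k], set()).add(i)
        from .seq_core import revcomp as _rc

        hits = {}
        for r1, r2 in pairs:
            for read in (r1, r2):
                cand: set[int] = set()
                for s in (read.seq, _rc(read.seq)):
                    for j in range(0, len(s) - k + 1):
                        cand |= index.get(s[j : j + k], set())
                if not cand:
                    continue
                subjects = [reference[i] for i in sorted(cand)]
                hit = align_local_nt(read, subjects, scoring)
                if hit is not None:
                    hits[read.id] = [hit]
        return hits

    manifest = None
    if config.simulate:
        logger.info("stage simulate: %d genes, seed %d", config.sim.n_genes, config.sim.seed)
        paths = simulate_dataset(config.sim, out / "sim")
        transcripts = read_fasta(paths["transcripts"])
        orthologs = read_fasta(paths["orthologs"])
        pairs = read_fastq_pairs(paths["reads_r1"], paths["reads_r2"])
        set_b = read_protein_set(paths["setb_fasta"], paths["setb_meta"])
        single_isoform = [
            s for s in paths["single_isoform"].read_text().splitlines() if s
        ]
        manifest = TruthManifest.read_tsv(paths["truth"])
    else:
        logger.info("stage load: reading user-supplied inputs")
        transcripts = read_fasta(config.transcripts)
        orthologs = read_fasta(config.orthologs)
        pairs = (
            read_fastq_pairs(config.reads_r1, config.reads_r2)
            if config.reads_r1 and config.reads_r2
            else []
        )
        set_b = (
            read_protein_set(config.setb_fasta, config.setb_meta)
            if config.setb_fasta
            else []
        )
        single_isoform = (
            [s for s in Path(config.single_isoform).read_text().splitlines() if s]
            if config.single_isoform
            else []
        )

    # --- read filtering against the mRNA reference (the contig set) -------
    filter_report = None
    if pairs:
        logger.info("stage filter: %d pairs", len(pairs))
        hits_by_read = _seeded_read_hits(pairs, transcripts)
        policy = FilterPolicy(
            min_len=config.min_len,
            max_len=config.max_len,
            drop_unaligned=config.drop_unaligned,
        )
        kept, filter_report = filter_pairs(pairs, hits_by_read, policy)
        write_filtered_fastq(kept, out / "filtered_R1.fastq", out / "filtered_R2.fastq")
        (out / "filter_report.tsv").write_text(filter_report.to_tsv())
        logger.info("stage filter done: kept %d/%d pairs",
                    filter_report.n_pairs_kept, filter_report.n_pairs_in)

    # --- contig statistics (assembly is delegated; contigs given) ---------
    stats = contig_stats([len(t.seq) for t in transcripts])
    (out / "contig_stats.tsv").write_text(
        "sample\tn_contigs\tn50\tmean_length\ttotal_length\n"
        + stats.to_tsv_row(config.sample) + "\n"
    )
    logger.info("stage stats: %d contigs, N50 %d", stats.n_contigs, stats.n50)

    # --- annotation --------------------------------------------------------
    logger.info("stage annotate: %d transcripts vs %d orthologs",
                len(transcripts), len(orthologs))
    annotations, summary = annotate_transcripts(
        transcripts,
        orthologs,
        min_identity=config.min_identity,
        max_length_diff=config.max_length_diff,
    )
    write_annotations(annotations, out / "annotation")
    logger.info("stage annotate done: %d accepted", summary.n_annotated)

    # --- comparison of the two annotation sets -----------------------------
    comparison: dict[str, Any] = {}
    if set_b:
        logger.info("stage compare: %d set-B proteins", len(set_b))
        set_a = [
            ProteinSetEntry(
                protein_id=a.transcript_id,
                seq=a.protein,
                gene_symbol=a.gene_symbol,
            )
            for a in annotations
            if a.status == "accepted"
        ]
        if set_a:
            summ_a = compare_to_reference(set_a, orthologs, config.max_targets)
            summ_b = compare_to_reference(set_b, orthologs, config.max_targets)
            set_b_sym = filter_by_symbol(set_b)
            summ_b_sym = (
                compare_to_reference(set_b_sym, orthologs, config.max_targets)
                if set_b_sym
                else None
            )
            comparison["assembled transcripts"] = summ_a
            comparison["all set B"] = summ_b
            if summ_b_sym is not None:
                comparison["set B with gene symbols"] = summ_b_sym
            genes, iso_a, iso_b = single_isoform_overlap(summ_a, summ_b, single_isoform)
            comparison["assembled, single-isoform overlap"] = iso_a
            comparison["set B, single-isoform overlap"] = iso_b
            comparison["single_isoform_genes"] = genes
            a_symbols = {e.gene_symbol for e in set_a if e.gene_symbol}
            comparison["missing_in_b"] = missing_genes(a_symbols, summ_b)
            b_symbols = {e.gene_symbol for e in set_b if e.gene_symbol}
            comparison["missing_in_a"] = missing_genes(b_symbols, summ_a)

            summ_a.to_tsv(out / "comparison_setA.tsv")
            summ_b.to_tsv(out / "comparison_setB.tsv")
            (out / "missing_in_setB.txt").write_text(
                "".join(g + "\n" for g in comparison["missing_in_b"])
            )
            (out / "missing_in_setA.txt").write_text(
                "".join(g + "\n" for g in comparison["missing_in_a"])
            )

    truth_scores = (
        _score_vs_truth(annotations, manifest) if manifest is not None else {}
    )

    echo = yaml.safe_dump(
        {**config.values, "sim": dataclasses.asdict(config.sim)},
        sort_keys=True,
        default_flow_style=False,
    )
    report = RunReport(
        sample=config.sample,
        filter_report=filter_report,
        contig_stats_row=dataclasses.asdict(stats),
        annotation_summary=summary,
        comparison=comparison,
        truth_scores=truth_scores,
        config_echo=echo,
    )
    (out / "report.md").write_text(report.to_markdown())
    logger.info("pipeline complete; report at %s", out / "report.md")
    return report
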