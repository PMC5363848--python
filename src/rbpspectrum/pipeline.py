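"""End-to-end analysis: ingest, controls, model selection, scenarios, MTL.

``run_full_analysis`` wires the stage modules into the complete workflow:

1. ingest clusters (or generate a toy bundle) and extract sequences,
2. sample length-matched controls,
3. per-protein grid-searched spectrum models,
4. the same with engineered composition features,
5. partition into exclusive/common categories and run the four
   discrimination scenarios,
6. the domain-adapted combined model with its out-of-domain ROC matrix,
7. occurrence counts of the top discriminative k-mers per category.

Every emitted table is plain tab-separated text stamped with the config
hash and seed that produced it, so reruns are diffable.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import asdict, dataclass, field, replace

import pandas as pd

from . import evaluation, model, seqdata, simulate
from .model import GridSearchConfig

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_analysis"]


@dataclass
class RunConfig:
    """Paths, search settings and generator sizes for one full run.

    When ``genome_fasta``/BED paths are unset, a synthetic toy bundle of
    ``n_hur``/``n_ttp`` clusters is generated instead (seeded), so the
    pipeline runs without external data.
    """

    output_dir: str = "rbpspectrum_out"
    genome_fasta: str | None = None
    hur_bed: str | None = None
    ttp_bed: str | None = None
    utr_bed: str | None = None
    n_hur: int = 300
    n_ttp: int = 300
    shared_fraction: float = 0.2
    grid: GridSearchConfig = field(default_factory=GridSearchConfig)
    seed: int = 0

    def config_hash(self) -> str:
        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


def _stamp(config: RunConfig) -> str:
    return f"# config_hash={config.config_hash()}\tseed={config.seed}\n"


def _write_table(df: pd.DataFrame, path: str, config: RunConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        df.to_csv(fh, sep="\t", index=index)
    logger.info("wrote %s", path)


def _report_row(name: str, report: evaluation.MetricsReport) -> dict:
    return {
        "dataset": name,
        "success_rate": round(report.success_rate, 1),
        "balanced_success_rate": round(report.balanced_success_rate, 1),
        "sensitivity": round(report.sensitivity, 1),
        "ppv": round(report.ppv, 1),
        "roc": round(report.roc_auc, 1) if report.roc_auc is not None else None,
    }


def _load_inputs(config: RunConfig):
    """Return (genome, annotation, hur_intervals, ttp_intervals)."""
    if config.genome_fasta:
        for name in ("hur_bed", "ttp_bed", "utr_bed"):
            if getattr(config, name) is None:
                raise ValueError(f"genome_fasta set but {name} missing")
        genome = seqdata.read_fasta(config.genome_fasta)
        annotation = seqdata.TranscriptAnnotation.from_bed(config.utr_bed)
        return (
            genome,
            annotation,
            seqdata.read_bed(config.hur_bed),
            seqdata.read_bed(config.ttp_bed),
        )
    if any((config.hur_bed, config.ttp_bed, config.utr_bed)):
        raise ValueError("BED inputs given without genome_fasta")
    bundle = simulate.make_toy_bundle(
        config.n_hur, config.n_ttp, config.shared_fraction, seed=config.seed
    )
    return bundle.genome, bundle.utr_annotation, bundle.hur_intervals, bundle.ttp_intervals


def run_full_analysis(config: RunConfig) -> dict:
    """Execute the full workflow and write all report tables.

    Returns a dict of the in-memory results keyed by stage name.
    """
    os.makedirs(config.output_dir, exist_ok=True)
    out = lambda name: os.path.join(config.output_dir, name)  # noqa: E731
    results: dict = {}

    genome, annotation, hur_iv, ttp_iv = _load_inputs(config)

    datasets = {}
    for rbp, intervals in (("HuR", hur_iv), ("TTP", ttp_iv)):
        positives = seqdata.extract_sequences(
            genome, intervals, label="positive", domain=rbp
        )
        negatives = seqdata.generate_controls(
            intervals, annotation, genome,
            seed=config.seed + (1 if rbp == "HuR" else 2),
            domain=rbp,
        )
        datasets[rbp] = positives + negatives

    # Table: length summaries of the positive sets
    length_rows = []
    for rbp in ("HuR", "TTP"):
        positives = [r for r in datasets[rbp] if r.label == "positive"]
        s = seqdata.summarize_lengths(positives)
        length_rows.append(
            {"rbp": rbp, "n": s.count, "max_length": s.max,
             "min_length": s.min, "mean_length": s.mean}
        )
    _write_table(pd.DataFrame(length_rows), out("table_lengths.tsv"), config)
    results["lengths"] = length_rows

    # Per-protein grid-searched models, plain and with engineered features
    perf_rows, weight_rows = [], []
    best_params = {}
    for engineered in (False, True):
        for rbp in ("HuR", "TTP"):
            grid = replace(config.grid, engineered=engineered)
            res = model.grid_search(datasets[rbp], grid)
            tag = f"{rbp}{'+engineered' if engineered else ''}"
            perf_rows.append(_report_row(tag, res.holdout_report))
            for rank, (feat, w) in enumerate(
                model.feature_weights(res.model, 10), start=1
            ):
                weight_rows.append(
                    {"model": tag, "rank": rank, "feature": feat,
                     "weight": round(w, 4)}
                )
            model.save_model(res.model, out(f"model_{tag.replace('+', '_')}.txt"))
            if not engineered:
                best_params[rbp] = res.best_params
            results[f"grid_{tag}"] = res
    _write_table(pd.DataFrame(perf_rows), out("table_performance.tsv"), config)
    _write_table(pd.DataFrame(weight_rows), out("table_top_features.tsv"), config)

    # Partition into exclusive/common categories and run the four scenarios
    partition = seqdata.partition_clusters(hur_iv, ttp_iv)
    categories = {
        "hur_only": seqdata.extract_sequences(genome, partition.a_only, domain="HuR"),
        "ttp_only": seqdata.extract_sequences(genome, partition.b_only, domain="TTP"),
        "common": seqdata.extract_sequences(genome, partition.common, domain="HuR"),
    }
    scenario_rows = []
    for num, spec in evaluation.SCENARIOS.items():
        res = evaluation.run_scenario(spec, categories, config.grid)
        row = _report_row(spec.name, res.report)
        row["n_positive"] = sum(len(categories[c]) for c in spec.positive)
        row["n_negative"] = sum(len(categories[c]) for c in spec.negative)
        row["top_features"] = ",".join(f for f, _ in res.top_features)
        scenario_rows.append(row)
        results[f"scenario{num}"] = res
    _write_table(pd.DataFrame(scenario_rows), out("table_scenarios.tsv"), config)

    # Domain adaptation: per-domain and combined models, out-of-domain matrix
    params = dict(best_params.get("HuR", {"k1": 5, "k2": 5, "C": 1.0}))
    combined = model.train_combined(datasets["HuR"], datasets["TTP"], params)
    matrix_rows = []
    pooled = datasets["HuR"] + datasets["TTP"]
    for test_name, test_records in (
        ("HuR", datasets["HuR"]), ("TTP", datasets["TTP"]), ("Combined", pooled)
    ):
        row = {"test_data": test_name}
        for model_name, m in (
            ("M_H", combined.hur_model),
            ("M_T", combined.ttp_model),
            ("M_B", combined.combined_model),
        ):
            if test_name == "Combined" and model_name != "M_B":
                row[model_name] = None
                continue
            rep = model.out_of_domain_eval(m, test_records)
            row[model_name] = round(rep.roc_auc, 1)
        matrix_rows.append(row)
    _write_table(pd.DataFrame(matrix_rows), out("table_domain_adaptation.tsv"), config)
    model.save_model(combined.combined_model, out("model_combined.txt"))
    results["combined"] = combined

    # Occurrence counts of top discriminative k-mers across categories
    top_kmers = [
        f for f, _ in model.feature_weights(combined.combined_model, 20)
        if set(f) <= set("ACGU")
    ][:8] or ["AUUUA"]
    counts = evaluation.count_kmer_occurrences(top_kmers, categories)
    _write_table(counts, out("table_kmer_occurrences.tsv"), config, index=True)
    results["kmer_counts"] = counts

    return results
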