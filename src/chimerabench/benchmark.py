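"""One-command reproduction of the scaled-down benchmark study.

The full loop: build a synthetic annotated reference once; derive several
mutated genomes (SNVs, indels, reciprocal fusion translocations) with
truth; simulate paired-end RNA-seq per genome; profile reads against the
*reference* k-mer index to call candidate junctions and their features;
run the progressive-sampling read-level classification protocol; train a
random forest on the pooled unique candidates to provide the chimera
score; then score an independent genome, aggregate events, classify and
reclassify them, fit the event-level models, and sweep the score
threshold for precision/FDR.

Problem sizes default to desk scale (two 1 Mb chromosomes, 150 genes,
8 translocations and 50k read pairs per genome) so the whole study runs
in minutes on one CPU while preserving the class-imbalance regime of the
original benchmark (roughly a fifth to a quarter of unique candidates are
true chimeras).
"""

from __future__ import annotations

import dataclasses
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (
    METHODS,
    TOP3,
    FittedModel,
    aggregate_metrics,
    deduplicate,
    run_protocol,
    train_model,
)
from .events import (
    DEFAULT_THRESHOLDS,
    build_event_table,
    threshold_sweep,
    train_event_classifier,
)
from .kmer import GenomeKmerIndex
from .mutate import FusionTruth, MutatedGenome, MutationRates, mutate_genome
from .profiler import ProfilerParams, build_support, collect_read_features
from .reads import assign_expression, simulate_reads
from .reference import ReferenceBundle, ReferenceSpec, build_reference


@dataclass(frozen=True)
class BenchmarkConfig:
    reference: ReferenceSpec = ReferenceSpec()
    rates: MutationRates = MutationRates()
    profiler: ProfilerParams = ProfilerParams()
    n_genomes: int = 5
    n_translocations: int = 8
    n_pairs: int = 50_000
    read_length: int = 100
    fragment_mean: float = 250.0
    fragment_sd: float = 50.0
    base_error_rate: float = 0.002
    zipf_exponent: float = 0.6
    expressed_fraction: float = 0.85
    n_repeats: int = 3
    folds: int = 10
    score_threshold: float = 0.7
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    methods: tuple[str, ...] = METHODS
    runs: tuple[str, ...] | None = None  # None = all progressive runs
    master_seed: int = 0

    def __post_init__(self):
        if self.read_length not in (100, 200):
            raise ValueError("read_length must be 100 or 200")


def expand_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2^31) from one master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return [int(s % (2**31)) for s in state]


@dataclass
class GenomeData:
    tag: str
    mutated: MutatedGenome
    fusions: list[FusionTruth]  # event ids namespaced with the genome tag
    features: pd.DataFrame  # labelled candidate table (raw, pre-dedup)


def simulate_genome(
    reference: ReferenceBundle,
    index: GenomeKmerIndex,
    config: BenchmarkConfig,
    seed: int,
    tag: str,
) -> GenomeData:
    """Mutate, express, sequence and profile one genome."""
    sub = expand_seeds(seed, 3)
    mutated = mutate_genome(reference, config.rates, config.n_translocations, sub[0])
    profile = assign_expression(
        mutated.lifted_genes,
        config.n_pairs,
        config.zipf_exponent,
        config.expressed_fraction,
        seed=sub[1],
    )
    records = simulate_reads(
        mutated,
        profile,
        config.n_pairs,
        read_length=config.read_length,
        fragment_mean=config.fragment_mean,
        fragment_sd=config.fragment_sd,
        base_error_rate=config.base_error_rate,
        seed=sub[2],
    )
    support = build_support(records, config.profiler.k)
    features = collect_read_features(
        records, index, support, mutated.fusions, reference.repeats, config.profiler
    )
    # Namespace truth events so pooled genomes stay distinguishable.
    rename = {f.event_id: f"{tag}:{f.event_id}" for f in mutated.fusions}
    fusions = [
        dataclasses.replace(
            f, event_id=rename[f.event_id], reciprocal_id=rename[f.reciprocal_id]
        )
        for f in mutated.fusions
    ]
    features = features.assign(
        event_id=features["event_id"].map(lambda e: rename.get(e, "."))
    )
    return GenomeData(tag=tag, mutated=mutated, fusions=fusions, features=features)


def audit_table(raw_tables: list[pd.DataFrame], dedup_tables: list[pd.DataFrame]) -> pd.DataFrame:
    """Candidate-count audit in the shape of the progressive-sampling table:
    all/unique candidate counts, % unique and % true per run."""
    rows = []
    for run_idx in range(1, len(raw_tables) + 1):
        raw = pd.concat(raw_tables[:run_idx], ignore_index=True)
        ded = pd.concat(dedup_tables[:run_idx], ignore_index=True)
        at, af = int(raw["label"].sum()), int((~raw["label"]).sum())
        ut, uf = int(ded["label"].sum()), int((~ded["label"]).sum())
        rows.append(
            {
                "run_id": f"r{run_idx}",
                "all_true": at,
                "all_false": af,
                "unique_true": ut,
                "unique_false": uf,
                "pct_unique": 100.0 * (ut + uf) / (at + af) if at + af else np.nan,
                "pct_true_unique": 100.0 * ut / (ut + uf) if ut + uf else np.nan,
            }
        )
    return pd.DataFrame(rows)


def score_candidates(model: FittedModel, features: pd.DataFrame) -> pd.DataFrame:
    return features.assign(score=model.predict_scores(features))


@dataclass
class BenchmarkResult:
    config: BenchmarkConfig
    reference: ReferenceBundle
    genomes: list[GenomeData]
    dedup_tables: list[pd.DataFrame]
    read_points: pd.DataFrame
    read_summary: pd.DataFrame
    audit: pd.DataFrame
    chimera_model: FittedModel | None = None
    independent: GenomeData | None = None
    independent_points: pd.DataFrame | None = None
    event_tables: list[pd.DataFrame] = field(default_factory=list)
    event_points: pd.DataFrame | None = None
    sweep: pd.DataFrame | None = None
    timings: dict[str, float] = field(default_factory=dict)


def run_benchmark(
    config: BenchmarkConfig = BenchmarkConfig(),
    stages: tuple[str, ...] = ("models", "events", "sweep"),
    out_dir: str | Path | None = None,
    make_plots: bool = False,
    verbose: bool = False,
) -> BenchmarkResult:
    """Run the study end to end (stage failures name the stage)."""
    timings: dict[str, float] = {}
    seeds = expand_seeds(config.master_seed, config.n_genomes + 3)

    def _log(msg: str) -> None:
        if verbose:
            print(f"[chimera-bench] {msg}", flush=True)

    def _stage(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                _log(f"stage {name} ...")
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self_inner.t0
                if exc is not None:
                    raise RuntimeError(f"benchmark stage '{name}' failed: {exc}") from exc
                _log(f"stage {name} done in {timings[name]:.1f}s")

        return _Timer()

    with _stage("reference"):
        reference = build_reference(config.reference, seeds[0])
        index = GenomeKmerIndex(
            reference.sequences, config.profiler.k, config.profiler.max_locations
        )

    genomes: list[GenomeData] = []
    with _stage("genomes"):
        for g in range(config.n_genomes):
            genomes.append(
                simulate_genome(reference, index, config, seeds[1 + g], tag=f"g{g + 1}")
            )
            _log(f"  genome g{g + 1}: {len(genomes[-1].features)} candidates")

    dedup_tables = [deduplicate(g.features) for g in genomes]
    audit = audit_table([g.features for g in genomes], dedup_tables)

    read_points = pd.DataFrame()
    read_summary = pd.DataFrame()
    if "models" in stages:
        with _stage("read_models"):
            read_points = run_protocol(
                dedup_tables,
                methods=config.methods,
                features=TOP3,
                n_repeats=config.n_repeats,
                folds=config.folds,
                base_seed=seeds[-1],
                runs=list(config.runs) if config.runs is not None else None,
            )
            read_summary = aggregate_metrics(read_points)

    result = BenchmarkResult(
        config=config,
        reference=reference,
        genomes=genomes,
        dedup_tables=dedup_tables,
        read_points=read_points,
        read_summary=read_summary,
        audit=audit,
        timings=timings,
    )

    if "events" in stages or "sweep" in stages:
        with _stage("chimera_model"):
            pooled = pd.concat(dedup_tables, ignore_index=True)
            result.chimera_model = train_model(
                pooled, "rf", TOP3, folds=config.folds, seed=seeds[-2]
            )
        with _stage("independent_genome"):
            result.independent = simulate_genome(
                reference, index, config, seeds[-3], tag="g_test"
            )
            result.independent_points = independent_test(
                dedup_tables, result.independent, config, base_seed=seeds[-2]
            )

    if "events" in stages:
        with _stage("events"):
            tables = []
            for g in genomes:
                scored = score_candidates(result.chimera_model, g.features)
                tables.append(
                    build_event_table(
                        scored,
                        reference.genes,
                        g.fusions,
                        threshold=config.score_threshold,
                        cluster_tolerance=config.profiler.tolerance,
                        tolerance=config.profiler.tolerance,
                    )
                )
            result.event_tables = tables
            usable = [t for t in tables if len(t) > 1]
            if len(usable) >= 2 and pd.concat(usable)["label"].nunique() == 2:
                result.event_points = train_event_classifier(
                    usable,
                    methods=config.methods,
                    n_repeats=config.n_repeats,
                    folds=config.folds,
                    base_seed=seeds[-2],
                )

    if "sweep" in stages:
        with _stage("sweep"):
            scored = score_candidates(result.chimera_model, result.independent.features)
            result.sweep = threshold_sweep(
                scored,
                reference.genes,
                result.independent.fusions,
                thresholds=config.thresholds,
                cluster_tolerance=config.profiler.tolerance,
                tolerance=config.profiler.tolerance,
            )

    if out_dir is not None:
        write_report(result, out_dir, make_plots=make_plots)
    return result


def independent_test(
    dedup_tables: list[pd.DataFrame],
    independent: GenomeData,
    config: BenchmarkConfig,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Train final-run models on all pooled genomes and score a fresh genome.

    Near-random performance triggers a warning: it is the signature of a
    test genome whose reference (or species) does not match the models'.
    """
    from .classify import evaluate

    pooled = pd.concat(dedup_tables, ignore_index=True)
    test = deduplicate(independent.features)
    rows = []
    for method in config.methods:
        model = train_model(pooled, method, TOP3, folds=config.folds, seed=base_seed)
        res = evaluate(model, test)
        rows.append(res)
    out = pd.DataFrame(rows)
    if out["AUC"].mean() < 0.6:
        warnings.warn(
            "independent test performs near randomly (mean AUC "
            f"{out['AUC'].mean():.2f}); the test genome likely does not match "
            "the training reference"
        )
    return out


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------


def write_report(result: BenchmarkResult, out_dir: str | Path, make_plots: bool = False) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.audit.to_csv(out / "audit.tsv", sep="\t", index=False)
    if len(result.read_points):
        result.read_points.to_csv(out / "read_points.tsv", sep="\t", index=False)
        result.read_summary.to_csv(out / "read_summary.tsv", sep="\t", index=False)
    if result.independent_points is not None:
        result.independent_points.to_csv(out / "independent.tsv", sep="\t", index=False)
    if result.event_points is not None:
        result.event_points.to_csv(out / "event_points.tsv", sep="\t", index=False)
    for i, t in enumerate(result.event_tables):
        t.drop(columns=["read_ids", "break_support"], errors="ignore").to_csv(
            out / f"events_g{i + 1}.tsv", sep="\t", index=False
        )
    if result.sweep is not None:
        result.sweep.to_csv(out / "sweep.tsv", sep="\t", index=False)
    _write_summary_md(result, out / "summary.md")
    if make_plots and len(result.read_points):
        _plot_metrics(result, out / "read_metrics.png")


def _write_summary_md(result: BenchmarkResult, path: Path) -> None:
    lines = ["# chimera-bench report", ""]
    lines += ["## Candidate audit (per progressive run)", "", result.audit.to_string(index=False), ""]
    if len(result.read_summary):
        lines += ["## Read-level metrics (mean over repeats)", "",
                  result.read_summary.to_string(index=False), ""]
    if result.independent_points is not None:
        lines += ["## Independent genome", "",
                  result.independent_points.to_string(index=False), ""]
    if result.sweep is not None:
        lines += ["## Chimera-score sweep", "", result.sweep.to_string(index=False), ""]
    lines += ["## Stage timings (s)", ""]
    lines += [f"- {k}: {v:.1f}" for k, v in result.timings.items()]
    path.write_text("\n".join(lines) + "\n")


def _plot_metrics(result: BenchmarkResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for metric, ax in zip(("ACC", "Kappa", "AUC"), axes):
        for method, sub in result.read_points.groupby("method"):
            means = sub.groupby("run_id")[metric].mean()
            ax.plot(means.index, means.values, marker="o", label=method)
        ax.set_title(metric)
        ax.set_xlabel("run")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
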