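"""Incremental feature selection over ranked SNP subsets.

For a fixed SNP ranking, nested top-m subsets (m = step, 2·step, …) are
each handed to a learner and scored; the resulting accuracy-vs-size curve
locates the optimal subset, defined as the smallest size attaining the
curve's maximum accuracy ("ensure performance while minimising the number
of SNPs"). The full grid crosses every scorer with every learner —
3 scorers x 4 learners by default, yielding 12 curves and 12 optima.

The default sweep step is 10 SNPs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .feature_scoring import MicConfig, ScoreTable, rank_features
from .io_formats import GenotypeMatrix, PhenotypeTable
from .learners import EvalMetrics, LearnerSpec, Protocol, evaluate

DEFAULT_STEP = 10


@dataclass
class IFSCurve:
    """Evaluation metrics as a function of ranked-subset size."""

    method: str
    learner: str
    subset_sizes: list[int]
    metrics: list[EvalMetrics]

    def __post_init__(self) -> None:
        if len(self.subset_sizes) != len(self.metrics):
            raise ValueError("sizes and metrics must align")
        if any(
            b <= a for a, b in zip(self.subset_sizes, self.subset_sizes[1:])
        ):
            raise ValueError("subset sizes must be strictly increasing")

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([m.accuracy for m in self.metrics])

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "learner": self.learner,
            "subset_sizes": [int(s) for s in self.subset_sizes],
            "metrics": [m.to_dict() for m in self.metrics],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "IFSCurve":
        return cls(
            d["method"],
            d["learner"],
            [int(s) for s in d["subset_sizes"]],
            [EvalMetrics.from_dict(m) for m in d["metrics"]],
        )


def select_optimal(curve: IFSCurve) -> tuple[int, EvalMetrics]:
    """Smallest subset size attaining the curve's maximum accuracy."""
    if not curve.subset_sizes:
        raise ValueError("empty IFS curve")
    acc = curve.accuracies
    best = int(np.argmax(acc))  # argmax takes the first (smallest) maximiser
    return curve.subset_sizes[best], curve.metrics[best]


def ifs_curve(
    ranked: ScoreTable,
    features: np.ndarray,
    target: np.ndarray,
    spec: LearnerSpec,
    protocol: Protocol = Protocol(),
    step: int = DEFAULT_STEP,
    max_features: int | None = None,
    features_test: np.ndarray | None = None,
    target_test: np.ndarray | None = None,
) -> IFSCurve:
    """Sweep nested top-m subsets of one ranking with one learner.

    ``features`` columns must align with ``ranked`` rows (same SNP order);
    the hold-out protocol additionally takes test-set features aligned the
    same way.
    """
    X = np.asarray(features, dtype=float)
    p = len(ranked)
    if X.shape[1] != p:
        raise ValueError("feature columns do not align with the ranking")
    if step < 1:
        raise ValueError("step must be >= 1")
    if step > p:
        raise ValueError(f"step {step} exceeds the number of SNPs {p}")
    if max_features is None:
        max_features = p
    if max_features > p:
        raise ValueError("max_features exceeds the number of SNPs")
    rank_order = np.argsort(ranked.ranks, kind="stable")
    sizes = list(range(step, max_features + 1, step))
    metrics = []
    for m in sizes:
        cols = rank_order[:m]
        metrics.append(
            evaluate(
                spec,
                X[:, cols],
                target,
                protocol,
                None if features_test is None else np.asarray(features_test)[:, cols],
                target_test,
            )
        )
    return IFSCurve(ranked.method, spec.kind, sizes, metrics)


@dataclass
class GridResult:
    """All scorer x learner IFS curves plus their optima and run seeds."""

    curves: list[IFSCurve]
    optimal_sizes: dict[str, int]
    optimal_metrics: dict[str, EvalMetrics]
    seeds: dict[str, int] = field(default_factory=dict)

    @staticmethod
    def pair_key(method: str, learner: str) -> str:
        return f"{method}+{learner}"

    def curve(self, method: str, learner: str) -> IFSCurve:
        for c in self.curves:
            if c.method == method and c.learner == learner:
                return c
        raise KeyError(f"no curve for {method}+{learner}")

    def to_records(self) -> list[dict]:
        """One record per pair, mirroring the optimal-subset report columns."""
        records = []
        for c in self.curves:
            key = self.pair_key(c.method, c.learner)
            m = self.optimal_metrics[key]
            records.append(
                {
                    "method": c.method,
                    "learner": c.learner,
                    "optimal_features": self.optimal_sizes[key],
                    "accuracy": m.accuracy,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
            )
        return records

    def to_dict(self) -> dict:
        return {
            "curves": [c.to_dict() for c in self.curves],
            "optimal_sizes": self.optimal_sizes,
            "optimal_metrics": {
                k: m.to_dict() for k, m in self.optimal_metrics.items()
            },
            "seeds": self.seeds,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridResult":
        return cls(
            [IFSCurve.from_dict(c) for c in d["curves"]],
            {k: int(v) for k, v in d["optimal_sizes"].items()},
            {k: EvalMetrics.from_dict(m) for k, m in d["optimal_metrics"].items()},
            {k: int(v) for k, v in d.get("seeds", {}).items()},
        )


def run_grid(
    g: GenotypeMatrix,
    pheno: PhenotypeTable,
    methods: list[str],
    learner_specs: list[LearnerSpec],
    protocol: Protocol = Protocol(),
    mode: str = "categorical",
    step: int = DEFAULT_STEP,
    max_features: int | None = None,
    mic_cfg: MicConfig | None = None,
    test_sample_ids: list[str] | None = None,
) -> GridResult:
    """Full scorer x learner sweep on one dataset.

    ``pheno`` must carry levels (quartile-discretized). In hold-out mode,
    ``test_sample_ids`` names the held-out samples; rankings are computed
    from the training samples only. Every learner's task is forced to
    match ``mode`` (quantitative -> regress, categorical -> classify).
    """
    if not methods or not learner_specs:
        raise ValueError("need at least one method and one learner")
    if pheno.levels is None:
        raise ValueError("phenotype must be discretized first")
    pheno = pheno.aligned_to(g.sample_ids)

    if protocol.kind == "holdout":
        if not test_sample_ids:
            raise ValueError("holdout protocol requires test_sample_ids")
        test_set = set(test_sample_ids)
        train_idx = [i for i, s in enumerate(g.sample_ids) if s not in test_set]
        test_idx = [i for i, s in enumerate(g.sample_ids) if s in test_set]
        if len(test_idx) != len(test_set):
            raise ValueError("some test sample ids are absent from the genotypes")
    else:
        train_idx = list(range(g.n_samples))
        test_idx = []

    X = g.dosages.astype(float)
    X_train = X[train_idx]
    X_test = X[test_idx] if test_idx else None
    task = "regress" if mode == "quantitative" else "classify"
    y_all = pheno.values if task == "regress" else pheno.levels
    y_train = y_all[train_idx]
    y_test = y_all[test_idx] if test_idx else None
    pheno_train = PhenotypeTable(
        [g.sample_ids[i] for i in train_idx],
        pheno.values[train_idx],
        pheno.levels[train_idx],
    )

    curves: list[IFSCurve] = []
    optimal_sizes: dict[str, int] = {}
    optimal_metrics: dict[str, EvalMetrics] = {}
    seeds: dict[str, int] = {"protocol": protocol.seed}
    for method in methods:
        ranked = rank_features(
            g.subset_samples(train_idx), pheno_train, method, mode, mic_cfg
        )
        for spec in learner_specs:
            spec = LearnerSpec(
                kind=spec.kind,
                task=task,
                k_neighbors=spec.k_neighbors,
                n_trees=spec.n_trees,
                seed=spec.seed,
                svm_c=spec.svm_c,
                svm_kernel=spec.svm_kernel,
            )
            curve = ifs_curve(
                ranked,
                X_train,
                y_train,
                spec,
                protocol,
                step,
                max_features,
                X_test,
                y_test,
            )
            size, metrics = select_optimal(curve)
            key = GridResult.pair_key(method, spec.kind)
            curves.append(curve)
            optimal_sizes[key] = size
            optimal_metrics[key] = metrics
            seeds[key] = spec.seed
    return GridResult(curves, optimal_sizes, optimal_metrics, seeds)
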