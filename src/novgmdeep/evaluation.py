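"""Metrics and the cross-validated evaluation protocol.

Metrics are the three the genomic-selection literature reports:

* Pearson correlation ``rho = cov(X, Y) / (sigma_X sigma_Y)`` between
  predicted and observed phenotypes,
* mean absolute error ``MAE = (1/N) sum_i |P_i - O_i|`` in raw trait units,
* population standard deviation (divisor N) of the per-sample absolute
  errors.

The protocol: accessions are split 80/20 into training and test sets; the
test set is held out before any model development. The training portion is
partitioned into 3 folds; each round trains on two folds, early-stops on the
held-out fold, and saves the best-validation-MAE model, giving three models.
Each model's predictions are correlated with the observed test phenotypes
and the three correlation values (not the predictions) are averaged into the
headline PCC. The single model with the lowest validation MAE supplies the
reported test MAE and the SD of its absolute errors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .model import ModelSpec, TrainedModel, build_and_fit, predict as model_predict

__all__ = [
    "pcc",
    "mae",
    "sd_population",
    "SplitPlan",
    "FoldPlan",
    "EvalReport",
    "make_split",
    "make_folds",
    "cross_validate",
    "evaluate_on_test",
    "run_protocol",
]


def pcc(X, Y) -> float:
    """Pearson correlation coefficient, cov(X, Y) / (sd_X * sd_Y).

    Raises on vectors shorter than 2 or with zero standard deviation (the
    correlation is undefined there; it is never silently reported as 0).
    """
    x = np.asarray(X, dtype=float)
    y = np.asarray(Y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("X and Y must be 1D vectors of equal length")
    if len(x) < 2:
        raise ValueError("PCC needs at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt((xc * xc).mean()))
    sy = float(np.sqrt((yc * yc).mean()))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("PCC undefined: at least one vector is constant (zero SD)")
    return float((xc * yc).mean() / (sx * sy))


def mae(P, O) -> float:
    """Mean absolute error between predicted and observed values."""
    p = np.asarray(P, dtype=float)
    o = np.asarray(O, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("MAE of empty vectors is undefined")
    return float(np.abs(p - o).mean())


def sd_population(x) -> float:
    """Population standard deviation (divisor N)."""
    v = np.asarray(x, dtype=float)
    if v.size == 0:
        raise ValueError("SD of an empty vector is undefined")
    return float(np.sqrt(((v - v.mean()) ** 2).mean()))


@dataclass(frozen=True)
class SplitPlan:
    """A disjoint train/test partition of accession indices."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    ratio: float
    seed: int

    def __post_init__(self) -> None:
        train, test = set(self.train_indices), set(self.test_indices)
        if train & test:
            raise ValueError("train and test indices overlap")


@dataclass(frozen=True)
class FoldPlan:
    """A balanced k-way partition of the training indices."""

    folds: tuple[tuple[int, ...], ...]
    seed: int

    @property
    def k(self) -> int:
        return len(self.folds)


def make_split(n: int, ratio: float = 0.8, seed: int = 0) -> SplitPlan:
    """Random train/test split; |train| = round-half-up(ratio * n)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    if n < 5:
        raise ValueError("need at least 5 accessions to split")
    n_train = int(np.floor(ratio * n + 0.5))
    perm = np.random.default_rng(seed).permutation(n)
    return SplitPlan(
        train_indices=tuple(int(i) for i in perm[:n_train]),
        test_indices=tuple(int(i) for i in perm[n_train:]),
        ratio=ratio,
        seed=seed,
    )


def make_folds(train_indices, k: int = 3, seed: int = 0) -> FoldPlan:
    """Random balanced partition into k folds (sizes differ by at most 1)."""
    idx = list(train_indices)
    if k < 2:
        raise ValueError("k must be at least 2")
    if len(idx) < k:
        raise ValueError(f"{len(idx)} indices cannot form {k} folds")
    perm = np.random.default_rng(seed).permutation(len(idx))
    shuffled = [idx[i] for i in perm]
    folds = tuple(
        tuple(int(v) for v in shuffled[f::k]) for f in range(k)
    )
    return FoldPlan(folds=folds, seed=seed)


def cross_validate(
    tensor,
    y,
    spec: ModelSpec,
    folds: FoldPlan,
    seed: int = 0,
) -> list[TrainedModel]:
    """Train one model per cross-validation round.

    ``tensor``/``y`` must contain training accessions only — the test set is
    left out before this function is ever called. Round f trains on the
    other k-1 folds and early-stops on fold f; each returned model carries
    its best validation MAE.
    """
    from .model import _as_array

    X = _as_array(tensor)
    y = np.asarray(y, dtype=float)
    models: list[TrainedModel] = []
    all_train = sorted(i for fold in folds.folds for i in fold)
    pos = {orig: row for row, orig in enumerate(all_train)}
    for f, fold in enumerate(folds.folds):
        if len(fold) == 0:
            raise ValueError(f"fold {f} is empty")
        val_rows = [pos[i] for i in fold]
        train_rows = [pos[i] for other in folds.folds if other is not fold for i in other]
        # rows of `tensor` are assumed to be ordered like sorted(train indices)
        model = build_and_fit(
            spec,
            (X[train_rows], y[train_rows]),
            (X[val_rows], y[val_rows]),
            seed=seed + f,
        )
        models.append(model)
    return models


@dataclass
class EvalReport:
    """Per-fold and averaged test metrics plus the run manifest."""

    per_fold_pcc: list[float]
    mean_pcc: float
    test_mae: float
    test_sd_abs_err: float
    best_model_index: int
    trait_name: str = ""
    scheme_id: str = ""
    manifest: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def evaluate_on_test(models, test: tuple, **report_fields) -> EvalReport:
    """Score saved models on the held-out test set.

    The headline PCC is the arithmetic mean of the per-model test
    correlations (correlations are averaged, predictions are never
    ensembled). Test MAE and the population SD of absolute errors come from
    the single model with the lowest validation MAE.
    """
    X_test, y_test = test
    y_test = np.asarray(y_test, dtype=float)
    if len(y_test) < 3:
        raise ValueError("test set must have at least 3 accessions for a stable PCC")
    per_pcc: list[float] = []
    preds: list[np.ndarray] = []
    for m in models:
        p = np.asarray(_model_predictions(m, X_test), dtype=float)
        preds.append(p)
        per_pcc.append(pcc(p, y_test))
    best = int(np.argmin([_val_mae(m) for m in models]))
    abs_err = np.abs(preds[best] - y_test)
    return EvalReport(
        per_fold_pcc=[float(v) for v in per_pcc],
        mean_pcc=float(np.mean(per_pcc)),
        test_mae=float(abs_err.mean()),
        test_sd_abs_err=sd_population(abs_err),
        best_model_index=best,
        **report_fields,
    )


def _model_predictions(m, X):
    if isinstance(m, TrainedModel):
        return model_predict(m, X)
    return m.predict(X)  # any object with a predict method works


def _val_mae(m) -> float:
    if isinstance(m, TrainedModel):
        return m.best_val_mae
    return float(getattr(m, "best_val_mae", np.inf))


def run_protocol(
    tensor,
    y,
    spec: ModelSpec | None = None,
    *,
    ratio: float = 0.8,
    k: int = 3,
    split_seed: int = 0,
    fold_seed: int = 0,
    model_seed: int = 0,
    trait_name: str = "",
    scheme_id: str = "",
) -> tuple[EvalReport, list[TrainedModel]]:
    """End-to-end protocol: 80/20 split, 3-fold CV, averaged test PCC.

    Returns the report and the three saved models. The test rows never enter
    any training or validation fold.
    """
    from .model import _as_array, default_spec

    spec = spec or default_spec()
    X = _as_array(tensor)
    y = np.asarray(y, dtype=float)
    split = make_split(X.shape[0], ratio=ratio, seed=split_seed)
    folds = make_folds(split.train_indices, k=k, seed=fold_seed)
    train_rows = sorted(split.train_indices)
    models = cross_validate(X[train_rows], y[train_rows], spec, folds, seed=model_seed)
    test_rows = list(split.test_indices)
    spec_hash = hashlib.sha256(repr(spec).encode()).hexdigest()[:12]
    report = evaluate_on_test(
        models,
        (X[test_rows], y[test_rows]),
        trait_name=trait_name,
        scheme_id=scheme_id,
        manifest={
            "split_seed": split_seed,
            "fold_seed": fold_seed,
            "model_seed": model_seed,
            "ratio": ratio,
            "k": k,
            "n_accessions": int(X.shape[0]),
            "n_markers": int(X.shape[1]),
            "spec_hash": spec_hash,
        },
    )
    return report, models
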