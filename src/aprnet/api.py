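"""High-level modelling interface.

:class:`AggregationNet` is constructed from a labeled hexapeptide dataset and
holds everything needed to train the predictor (feature table, architecture,
split/fold policy). Its :meth:`~AggregationNet.fit` trains the five
cross-validation networks and returns an :class:`AggregationNetResults`
carrying the fitted ensemble, per-fold training histories, the held-out test
performance, and the Youden-J default threshold; profiling whole sequences,
APR calling, evaluation against annotations, plotting and persistence all
hang off the results object.

Example
-------
>>> from aprnet import synthetic, AggregationNet
>>> data = synthetic.gen_hexapeptides(synthetic.SyntheticSpec(seed=7))
>>> res = AggregationNet(data).fit(seed=7, max_epochs=30)
>>> print(res.summary())            # doctest: +SKIP
>>> prof = res.profile("MKVIFLLVVF...")  # doctest: +SKIP
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import metrics, training
from .encoding import (
    FeatureTable,
    Hexapeptide,
    default_feature_table,
    encode_dataset,
    encode_hexapeptide,
)
from .io import AnnotatedProtein, apr_mask
from .model import (
    PUBLISHED_CONFIG,
    EnsembleModel,
    ModelConfig,
    load_model,
    save_model,
)
from .profiling import MIN_APR_LENGTH, APRCall, ResidueProfile, call_aprs, profile_sequence

__all__ = ["AggregationNet", "AggregationNetResults", "EvaluationReport"]


@dataclass
class EvaluationReport:
    """Per-protein and macro-averaged whole-sequence evaluation."""

    per_protein: pd.DataFrame  # columns: id, auroc, auprc, sov_apr, sov_non_apr
    threshold: float

    @property
    def macro(self) -> dict[str, float]:
        return {
            col: metrics.macro_average(self.per_protein[col])
            for col in ("auroc", "auprc", "sov_apr", "sov_non_apr")
        }


class AggregationNet:
    """Hexapeptide aggregation classifier (ensemble of bidirectional LSTMs).

    Parameters
    ----------
    data:
        Labeled hexapeptides (each a :class:`~aprnet.encoding.Hexapeptide`).
    config:
        Architecture/optimization hyperparameters; defaults to the published
        top-performing configuration.
    feature_table:
        Residue descriptor table; defaults to the built-in 36-descriptor set.
    standardize:
        Optionally z-score each descriptor using statistics of the training
        split only. Off by default (descriptors are used as stored).
    """

    def __init__(
        self,
        data: Sequence[Hexapeptide],
        config: ModelConfig = PUBLISHED_CONFIG,
        feature_table: FeatureTable | None = None,
        standardize: bool = False,
    ):
        if not data:
            raise ValueError("dataset must not be empty")
        self.data = list(data)
        self.config = config
        self.feature_table = feature_table or default_feature_table()
        self.standardize = standardize

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "AggregationNet":
        """Build from a DataFrame with ``sequence`` and ``label`` columns."""
        records = [
            Hexapeptide(str(row.sequence).upper(), int(row.label))
            for row in df.itertuples()
        ]
        return cls(records, **kwargs)

    def fit(
        self,
        seed: int = 0,
        test_fraction: float | None = 0.9,
        k: int = 5,
        max_epochs: int = training.DEFAULT_MAX_EPOCHS,
        patience: int = training.DEFAULT_PATIENCE,
        min_delta: float = training.DEFAULT_MIN_DELTA,
        class_weight: bool = False,
    ) -> "AggregationNetResults":
        """Split, cross-validate, train the ensemble, score the test split.

        ``test_fraction`` is the fraction kept for *training* (0.9 reproduces
        the 90/10 protocol); pass ``None`` to train on everything.
        """
        X, y = encode_dataset(self.data, self.feature_table)
        if test_fraction is not None:
            split = training.stratified_split(y, fraction=test_fraction, seed=seed)
            tr_idx, te_idx = split.train_indices, split.test_indices
        else:
            split = None
            tr_idx = np.arange(len(y))
            te_idx = np.array([], dtype=np.int64)
        scaler = None
        if self.standardize:
            mu = X[tr_idx].mean(axis=(0, 1))
            sd = X[tr_idx].std(axis=(0, 1))
            sd[sd == 0] = 1.0
            scaler = (mu, sd)
            X = (X - mu) / sd
        folds = training.make_folds(y[tr_idx], k=k, seed=seed)
        ensemble = training.train_crossval(
            X[tr_idx], y[tr_idx], self.config, folds, seed=seed,
            max_epochs=max_epochs, patience=patience, min_delta=min_delta,
            class_weight=class_weight,
            feature_table_id=self.feature_table.identifier(),
        )
        test_auroc = test_auprc = math.nan
        if te_idx.size and 0 < y[te_idx].sum() < te_idx.size:
            test_scores = ensemble.predict_batch(X[te_idx])
            test_auroc = metrics.roc_curve(test_scores, y[te_idx]).auc
            test_auprc = metrics.pr_curve(test_scores, y[te_idx]).auc
        return AggregationNetResults(
            ensemble=ensemble,
            feature_table=self.feature_table,
            config=self.config,
            seed=seed,
            split=split,
            folds=folds,
            test_auroc=test_auroc,
            test_auprc=test_auprc,
            scaler=scaler,
        )


@dataclass
class AggregationNetResults:
    """A fitted ensemble with its training record and evaluation helpers."""

    ensemble: EnsembleModel
    feature_table: FeatureTable
    config: ModelConfig
    seed: int
    split: training.SplitSpec | None = None
    folds: training.FoldPlan | None = None
    test_auroc: float = math.nan
    test_auprc: float = math.nan
    scaler: tuple[np.ndarray, np.ndarray] | None = None

    # -- prediction -------------------------------------------------------
    def _transform(self, X: np.ndarray) -> np.ndarray:
        if self.scaler is None:
            return X
        mu, sd = self.scaler
        return (X - mu) / sd

    @property
    def threshold(self) -> float | None:
        """Youden-J threshold computed on the training data at fit time."""
        return self.ensemble.threshold

    def predict(self, hexapeptides: Sequence[Hexapeptide | str]) -> np.ndarray:
        """Ensemble scores in [0, 1] for a batch of hexapeptides."""
        X = np.stack([
            encode_hexapeptide(h, self.feature_table).matrix for h in hexapeptides
        ])
        return self.ensemble.predict_batch(self._transform(X))

    def profile(self, sequence: str, sequence_id: str = "query",
                aux_channels=None) -> ResidueProfile:
        """Per-residue aggregation profile of a whole protein sequence."""
        if self.scaler is None:
            return profile_sequence(self.ensemble, self.feature_table, sequence,
                                    sequence_id, aux_channels)
        from .profiling import aggregate_per_residue, sequence_to_windows

        seq = sequence.upper()
        windows = sequence_to_windows(seq)
        X = self._transform(np.stack([
            encode_hexapeptide(w, self.feature_table).matrix for w in windows
        ]))
        scores, coverage = aggregate_per_residue(
            self.ensemble.predict_batch(X), len(seq))
        return ResidueProfile(sequence_id=sequence_id, sequence=seq,
                              scores=scores, coverage=coverage,
                              aux_channels=dict(aux_channels or {}))

    def aprs(self, profile: ResidueProfile, threshold: float | None = None,
             min_length: int = MIN_APR_LENGTH) -> list[APRCall]:
        """APR calls at the given (default: stored Youden-J) threshold."""
        thr = self.threshold if threshold is None else threshold
        if thr is None:
            raise ValueError("no stored threshold; pass one explicitly")
        return call_aprs(profile, thr, min_length)

    # -- evaluation -------------------------------------------------------
    def evaluate(self, proteins: Sequence[AnnotatedProtein],
                 threshold: float | None = None,
                 min_length: int = MIN_APR_LENGTH) -> EvaluationReport:
        """Whole-sequence benchmark against annotated APR intervals.

        Per protein: AuROCC and AuPRC of the per-residue scores against the
        union-of-intervals ground truth, and the two SOV scores of the called
        segmentation. Proteins on which a metric is undefined (e.g. no
        annotated APR) contribute NaN, excluded from the macro average.
        """
        thr = self.threshold if threshold is None else threshold
        if thr is None:
            raise ValueError("no stored threshold; pass one explicitly")
        rows = []
        for prot in proteins:
            prof = self.profile(prot.sequence, sequence_id=prot.id)
            truth = apr_mask(prot)
            auroc = auprc = math.nan
            if 0 < truth.sum() < truth.size:
                auroc = metrics.roc_curve(prof.scores, truth).auc
                auprc = metrics.pr_curve(prof.scores, truth).auc
            calls = call_aprs(prof, thr, min_length)
            pred = np.zeros(len(prof), dtype=np.int64)
            for c in calls:
                pred[c.start - 1:c.end] = 1
            sov = metrics.sov_both(pred, truth)
            rows.append({
                "id": prot.id, "auroc": auroc, "auprc": auprc,
                "sov_apr": sov.sov_apr, "sov_non_apr": sov.sov_non_apr,
            })
        return EvaluationReport(per_protein=pd.DataFrame(rows), threshold=thr)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        """Human-readable fit summary (statsmodels-style text table)."""
        lines = []
        w = 66
        lines.append("Aggregation-prone region predictor".center(w))
        lines.append("=" * w)
        lines.append(f"{'Ensemble members:':<34}{len(self.ensemble.members):>32}")
        lines.append(f"{'Architecture layers:':<34}{self.config.n_layers:>32}")
        widths = "x".join(str(n) for n in self.config.neurons_per_layer)
        lines.append(f"{'Layer widths:':<34}{widths:>32}")
        lines.append(f"{'Dropout / batch / lr:':<34}"
                     f"{f'{self.config.dropout} / {self.config.batch_size} / {self.config.learning_rate}':>32}")
        lines.append(f"{'Seed:':<34}{self.seed:>32}")
        lines.append("-" * w)
        for i, m in enumerate(self.ensemble.members):
            val = m.training_history["val_auroc"][m.stopping_epoch - 1]
            lines.append(
                f"fold {i}: stopped at epoch {m.stopping_epoch:>3}   "
                f"validation AuROCC {val:.4f}"
            )
        lines.append("-" * w)
        if self.threshold is not None:
            lines.append(f"{'Youden-J threshold (train):':<34}{self.threshold:>32.4f}")
        if not math.isnan(self.test_auroc):
            lines.append(f"{'Held-out test AuROCC:':<34}{self.test_auroc:>32.4f}")
            lines.append(f"{'Held-out test AuPRC:':<34}{self.test_auprc:>32.4f}")
        lines.append("=" * w)
        return "\n".join(lines)

    def plot_profile(self, profile: ResidueProfile, calls=None, ax=None,
                     threshold: float | None = None):
        """Plot a per-residue profile with called APRs shaded."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 3))
        pos = np.arange(1, len(profile) + 1)
        ax.plot(pos, profile.scores, lw=1.2, label="aggregation propensity")
        thr = threshold if threshold is not None else self.threshold
        if thr is not None:
            ax.axhline(thr, ls="--", lw=0.8, color="grey", label="threshold")
        for c in (calls or []):
            ax.axvspan(c.start, c.end, color="tab:red", alpha=0.2)
        for name, ch in profile.aux_channels.items():
            ax.plot(pos, ch, lw=0.8, ls=":", label=name)
        ax.set_xlabel("residue position")
        ax.set_ylabel("score")
        ax.set_ylim(0, 1)
        ax.set_title(profile.sequence_id)
        ax.legend(loc="upper right", fontsize=8)
        return ax

    # -- persistence ------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        """Persist the ensemble (manifest + member weights [+ scaler])."""
        path = save_model(self.ensemble, path)
        if self.scaler is not None:
            np.savez(Path(path) / "scaler.npz", mu=self.scaler[0], sd=self.scaler[1])
        return path

    @classmethod
    def load(cls, path: str | Path,
             feature_table: FeatureTable | None = None) -> "AggregationNetResults":
        path = Path(path)
        ensemble = load_model(path)
        if not isinstance(ensemble, EnsembleModel):
            raise ValueError(f"{path} holds a single network, not an ensemble")
        table = feature_table or default_feature_table()
        if ensemble.feature_table_id and ensemble.feature_table_id != table.identifier():
            raise ValueError(
                "feature table does not match the one the ensemble was "
                "trained with; pass the correct table to load()"
            )
        scaler = None
        scaler_path = path / "scaler.npz"
        if scaler_path.exists():
            with np.load(scaler_path) as npz:
                scaler = (npz["mu"], npz["sd"])
        return cls(
            ensemble=ensemble,
            feature_table=table,
            config=ensemble.members[0].config,
            seed=ensemble.members[0].seed,
            scaler=scaler,
        )
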