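"""Random-forest coding-potential model with the short-ORF shortcut.

The decision rule has two branches.  Transcripts whose longest forward-frame
ORF is shorter than 54 nt — the minimum observed for real mRNAs — are called
non-coding outright, bypassing the forest.  All other transcripts are scored
by a 300-tree random forest over the selected features; the non-coding score
is the fraction of trees voting for the non-coding class, and the call is
non-coding when that fraction reaches the decision threshold (ties go to
non-coding).  Non-coding training examples below the shortcut threshold are
excluded before fitting, since the shortcut already handles them.

Organisation follows the model/results idiom: :class:`CodingPotentialModel`
holds data and configuration, ``fit()`` returns a
:class:`CodingPotentialResults` carrying the fitted forest, the feature
ranking, prediction and importance methods, and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from . import feature_selection
from .errors import ConfigurationError, ValidationError
from .sequence_io import CODING, NONCODING

_BUNDLE_FORMAT = "lncrnapred-model-1"


@dataclass
class Prediction:
    """Per-transcript call: non-coding score, label, shortcut flag, features."""

    id: str
    noncoding_score: float
    predicted: str
    shortcut_applied: bool
    features: dict[str, float] = field(default_factory=dict)


class CodingPotentialModel:
    """Coding-potential classifier specification bound to training data.

    Parameters
    ----------
    X : DataFrame
        Feature matrix (89 canonical columns, or at least the selected
        features plus MaxORF), one row per transcript, ids as index.
    y : array-like of str
        Labels, CODING or NONCODING.
    selected_features : list of str, optional
        Feature subset for the forest.  When omitted, ``fit`` ranks all
        columns by the feature score criterion and keeps the top
        ``n_selected``.
    n_selected : int
        Size of the automatic selection (default 30).
    n_trees : int
        Forest size (default 300).
    orf_shortcut : int
        MaxORF threshold (nt) below which transcripts are called non-coding
        without consulting the forest (default 54).
    decision_threshold : float
        Minimum non-coding vote fraction for a non-coding call (default 0.5).
    """

    def __init__(
        self,
        X: pd.DataFrame,
        y,
        selected_features: Sequence[str] | None = None,
        n_selected: int = 30,
        n_trees: int = 300,
        orf_shortcut: int = 54,
        decision_threshold: float = 0.5,
    ):
        if n_trees < 1:
            raise ConfigurationError(f"n_trees must be >= 1, got {n_trees}")
        if not 0.0 < decision_threshold < 1.0:
            raise ConfigurationError(
                f"decision_threshold must lie in (0, 1), got {decision_threshold}"
            )
        self.X = X
        self.y = pd.Series(np.asarray(y), index=X.index, name="label")
        bad = set(self.y.unique()) - {CODING, NONCODING}
        if bad:
            raise ValidationError(f"unknown labels in y: {sorted(bad)}")
        self.selected_features = (
            list(selected_features) if selected_features is not None else None
        )
        self.n_selected = n_selected
        self.n_trees = n_trees
        self.orf_shortcut = orf_shortcut
        self.decision_threshold = decision_threshold

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "label", **kwargs
    ) -> "CodingPotentialModel":
        """Build from one DataFrame holding feature columns plus a label column."""
        y = df[label_col]
        X = df.drop(columns=[label_col])
        return cls(X, y, **kwargs)

    @classmethod
    def from_transcripts(cls, transcripts, **kwargs) -> "CodingPotentialModel":
        """Build from labelled Transcript objects (features extracted here)."""
        from .features import feature_frame

        X, y = feature_frame(transcripts)
        return cls(X, y, **kwargs)

    def fit(self, seed: int = 0) -> "CodingPotentialResults":
        """Select features if needed, filter shortcut cases, fit the forest."""
        ranking = None
        selected = self.selected_features
        if selected is None:
            ranking = feature_selection.fsc_scores(self.X, self.y)
            selected = feature_selection.select_top(ranking, self.n_selected)
        missing = [f for f in selected if f not in self.X.columns]
        if missing:
            raise ValidationError(f"selected features missing from X: {missing}")
        if "MaxORF" not in self.X.columns:
            raise ValidationError("X must contain the MaxORF column")

        # the shortcut already answers for short-ORF non-coding examples
        drop = (self.y == NONCODING) & (self.X["MaxORF"] < self.orf_shortcut)
        X_fit = self.X.loc[~drop, selected]
        y_fit = self.y.loc[~drop]
        classes = set(y_fit.unique())
        if classes != {CODING, NONCODING}:
            raise ValidationError(
                "training data must contain both classes after the shortcut "
                f"filter (got {sorted(classes)})"
            )
        forest = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features="sqrt",
            random_state=int(seed) % (2**31),
            n_jobs=1,
        )
        forest.fit(X_fit.to_numpy(), (y_fit == NONCODING).astype(int).to_numpy())
        metadata = {
            "format": _BUNDLE_FORMAT,
            "seed": int(seed),
            "n_train_input": int(len(self.y)),
            "n_train_used": int(len(y_fit)),
            "n_shortcut_filtered": int(drop.sum()),
            "class_counts": y_fit.value_counts().to_dict(),
        }
        return CodingPotentialResults(
            selected_features=list(selected),
            forest=forest,
            orf_shortcut=self.orf_shortcut,
            decision_threshold=self.decision_threshold,
            ranking=ranking,
            metadata=metadata,
        )


@dataclass
class CodingPotentialResults:
    """Fitted model: selected features, forest, thresholds, provenance."""

    selected_features: list[str]
    forest: RandomForestClassifier
    orf_shortcut: int
    decision_threshold: float
    ranking: feature_selection.FSCRanking | None = None
    metadata: dict = field(default_factory=dict)

    # -- prediction ------------------------------------------------------

    def noncoding_vote_fraction(self, X: pd.DataFrame) -> np.ndarray:
        """Fraction of trees voting non-coding, per row (forest branch only)."""
        Xv = X[self.selected_features].to_numpy()
        nc_index = float(list(self.forest.classes_).index(1))
        votes = np.stack([tree.predict(Xv) for tree in self.forest.estimators_])
        return (votes == nc_index).mean(axis=0)

    def predict(self, X: pd.DataFrame) -> list[Prediction]:
        """Score a batch of feature vectors (ids taken from the index).

        Rows with MaxORF below the shortcut threshold are called NONCODING
        with score 1.0 and the shortcut flag set; the rest are voted on by
        the forest and thresholded (ties to NONCODING).
        """
        missing = [
            f for f in self.selected_features + ["MaxORF"] if f not in X.columns
        ]
        if missing:
            raise ValidationError(f"missing feature columns: {missing}")
        shortcut = (X["MaxORF"] < self.orf_shortcut).to_numpy()
        scores = np.ones(len(X))
        if (~shortcut).any():
            scores[~shortcut] = self.noncoding_vote_fraction(X.loc[~shortcut])
        out: list[Prediction] = []
        for i, (rid, row) in enumerate(X.iterrows()):
            sc = bool(shortcut[i])
            score = 1.0 if sc else float(scores[i])
            label = NONCODING if sc or score >= self.decision_threshold else CODING
            out.append(
                Prediction(
                    id=str(rid),
                    noncoding_score=score,
                    predicted=label,
                    shortcut_applied=sc,
                    features={f: float(row[f]) for f in self.selected_features},
                )
            )
        return out

    def predict_labels(self, X: pd.DataFrame) -> np.ndarray:
        return np.array([p.predicted for p in self.predict(X)])

    def noncoding_scores(self, X: pd.DataFrame) -> np.ndarray:
        return np.array([p.noncoding_score for p in self.predict(X)])

    # -- diagnostics -----------------------------------------------------

    def permutation_importance(
        self, X: pd.DataFrame, y, repeats: int = 10, seed: int = 0
    ) -> pd.Series:
        """Held-out permutation importance per selected feature.

        Mean over repeats of (error with the column permuted - baseline
        error), where error is the misclassification rate of the full
        decision rule (shortcut included).  Sorted descending.
        """
        if repeats < 1:
            raise ConfigurationError(f"repeats must be >= 1, got {repeats}")
        y = np.asarray(y)
        rng = np.random.default_rng(seed)
        baseline = float(np.mean(self.predict_labels(X) != y))
        importances = {}
        for feat in self.selected_features:
            deltas = []
            for _ in range(repeats):
                Xp = X.copy()
                Xp[feat] = rng.permutation(Xp[feat].to_numpy())
                err = float(np.mean(self.predict_labels(Xp) != y))
                deltas.append(err - baseline)
            importances[feat] = float(np.mean(deltas))
        return pd.Series(importances).sort_values(ascending=False)

    def summary(self) -> str:
        """Human-readable account of the fitted model."""
        md = self.metadata
        lines = [
            "Coding-potential model (random forest + short-ORF shortcut)",
            "=" * 59,
            f"trees:               {len(self.forest.estimators_)}",
            f"selected features:   {len(self.selected_features)}",
            f"ORF shortcut:        MaxORF < {self.orf_shortcut} nt -> NONCODING",
            f"decision threshold:  noncoding vote fraction >= {self.decision_threshold}",
            f"training rows:       {md.get('n_train_input', '?')} "
            f"({md.get('n_shortcut_filtered', '?')} removed by shortcut filter)",
            f"fit seed:            {md.get('seed', '?')}",
            "",
            "top selected features: " + ", ".join(self.selected_features[:10]),
        ]
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        """Persist the fitted model as a single joblib bundle."""
        bundle = {
            "format": _BUNDLE_FORMAT,
            "selected_features": self.selected_features,
            "forest": self.forest,
            "orf_shortcut": self.orf_shortcut,
            "decision_threshold": self.decision_threshold,
            "metadata": self.metadata,
        }
        joblib.dump(bundle, path)

    @classmethod
    def load(cls, path) -> "CodingPotentialResults":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"model bundle not found: {path}")
        bundle = joblib.load(path)
        if not isinstance(bundle, dict) or bundle.get("format") != _BUNDLE_FORMAT:
            raise ValidationError(
                f"unrecognised model bundle format in {path} "
                f"(expected {_BUNDLE_FORMAT!r})"
            )
        return cls(
            selected_features=bundle["selected_features"],
            forest=bundle["forest"],
            orf_shortcut=bundle["orf_shortcut"],
            decision_threshold=bundle["decision_threshold"],
            metadata=bundle.get("metadata", {}),
        )


# -- functional surface mirroring the pipeline stages ----------------------

def train(
    X: pd.DataFrame,
    y,
    selected_features: Sequence[str] | None = None,
    n_trees: int = 300,
    seed: int = 0,
    orf_shortcut: int = 54,
    decision_threshold: float = 0.5,
) -> CodingPotentialResults:
    """Fit the forest on a labelled feature matrix (see CodingPotentialModel)."""
    model = CodingPotentialModel(
        X,
        y,
        selected_features=selected_features,
        n_trees=n_trees,
        orf_shortcut=orf_shortcut,
        decision_threshold=decision_threshold,
    )
    return model.fit(seed=seed)


def predict(results: CodingPotentialResults, X: pd.DataFrame) -> list[Prediction]:
    return results.predict(X)


def permutation_importance(
    results: CodingPotentialResults, X: pd.DataFrame, y, repeats: int = 10, seed: int = 0
) -> pd.Series:
    return results.permutation_importance(X, y, repeats=repeats, seed=seed)
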