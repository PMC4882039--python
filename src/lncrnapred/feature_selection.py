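"""Univariate feature ranking by the feature score criterion (FSC).

The FSC is a Golub-style separability score for a binary problem:
``|mu+ - mu-| / (sd+ + sd-)`` with per-class means and sample standard
deviations.  It is symmetric under swapping the class labels and invariant
under affine rescaling of a feature.  Degenerate denominators are resolved
without epsilons: a feature constant within both classes scores +inf when the
class means differ (a perfect separator) and 0 when they coincide
(uninformative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .sequence_io import NONCODING


@dataclass
class FSCRanking:
    """Ranked feature table: columns feature, score, mu_pos, sd_pos, mu_neg,
    sd_neg, sorted by score descending with ties broken by the input
    (canonical) feature order."""

    table: pd.DataFrame

    @property
    def features(self) -> list[str]:
        return list(self.table["feature"])

    @property
    def scores(self) -> pd.Series:
        return self.table.set_index("feature")["score"]

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "rank", np.arange(1, len(out) + 1))
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def fsc_scores(X: pd.DataFrame, y, positive_label: str = NONCODING) -> FSCRanking:
    """Score every column of X by the feature score criterion.

    ``y`` holds binary labels; ``positive_label`` marks the positive class
    (the score itself is label-symmetric).  Each class needs at least two
    samples for the sample standard deviation to exist.
    """
    y = np.asarray(y)
    pos = X.loc[y == positive_label]
    neg = X.loc[y != positive_label]
    if len(pos) < 2 or len(neg) < 2:
        raise ValidationError(
            "each class needs >= 2 samples for FSC "
            f"(got {len(pos)} positive, {len(neg)} negative)"
        )
    mu_p = pos.mean(axis=0)
    mu_n = neg.mean(axis=0)
    sd_p = pos.std(axis=0, ddof=1)
    sd_n = neg.std(axis=0, ddof=1)
    denom = sd_p + sd_n
    diff = (mu_p - mu_n).abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        score = diff / denom
    score = score.where(denom > 0, np.where(diff > 0, np.inf, 0.0))
    table = pd.DataFrame(
        {
            "feature": X.columns,
            "score": score.to_numpy(),
            "mu_pos": mu_p.to_numpy(),
            "sd_pos": sd_p.to_numpy(),
            "mu_neg": mu_n.to_numpy(),
            "sd_neg": sd_n.to_numpy(),
        }
    )
    # stable sort keeps canonical column order on ties
    table = table.sort_values("score", ascending=False, kind="mergesort")
    return FSCRanking(table=table.reset_index(drop=True))


def select_top(ranking: FSCRanking, p: int = 30) -> list[str]:
    """The first p feature names of the ranking, order preserved."""
    m = len(ranking.table)
    if not 1 <= p <= m:
        raise ConfigurationError(f"p = {p} outside [1, {m}]")
    return ranking.features[:p]
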