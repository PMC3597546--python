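"""Model/Results front end over the vector random forest.

`EnhancerForest` holds a training design (the N × M × 20 feature blocks and
their labels); `fit()` grows the ensemble and returns an
`EnhancerForestResults` carrying the fitted forest, its out-of-bag error,
permutation importance, and genome-scanning / peak-calling methods, with a
`summary()` table in the spirit of statistical modelling packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .forest import (
    DEFAULT_MIN_NODE,
    DEFAULT_N_TREES,
    ImportanceReport,
    VectorForest,
    fit_forest,
    load_forest,
    oob_error,
    oob_variable_importance,
    predict_votes,
    save_forest,
)
from .scan import EnhancerCall, VoteTrack, call_peaks, scan_genome
from .signal import BinnedTrack
from .training import ENHANCER, FeatureBlockMatrix

__all__ = ["EnhancerForest", "EnhancerForestResults"]


class EnhancerForest:
    """Enhancer-vs-non-enhancer vector random forest model.

    Parameters
    ----------
    training_set
        Feature blocks (N samples × M marks × 20 bins) with class labels.
    """

    def __init__(self, training_set: FeatureBlockMatrix):
        self.training_set = training_set

    @classmethod
    def from_feature_file(cls, path: str) -> "EnhancerForest":
        return cls(FeatureBlockMatrix.load(path))

    def fit(
        self,
        n_trees: int = DEFAULT_N_TREES,
        mtry: int | None = None,
        min_node: int = DEFAULT_MIN_NODE,
        seed: int = 0,
    ) -> "EnhancerForestResults":
        forest = fit_forest(
            self.training_set, n_trees=n_trees, mtry=mtry, min_node=min_node, seed=seed
        )
        return EnhancerForestResults(self, forest)


@dataclass
class EnhancerForestResults:
    """Fitted ensemble plus its internal diagnostics."""

    model: EnhancerForest
    forest: VectorForest
    _oob: tuple[float, int] | None = None

    @property
    def oob_error_(self) -> float:
        if self._oob is None:
            self._oob = oob_error(self.forest, self.model.training_set)
        return self._oob[0]

    @property
    def n_oob_excluded_(self) -> int:
        if self._oob is None:
            self._oob = oob_error(self.forest, self.model.training_set)
        return self._oob[1]

    def predict_votes(self, features: FeatureBlockMatrix | np.ndarray) -> np.ndarray:
        return predict_votes(self.forest, features)

    def importance(self, n_permutations: int = 5, seed: int = 0) -> ImportanceReport:
        return oob_variable_importance(
            self.forest, self.model.training_set, n_permutations, seed
        )

    def scan(self, tracks: list[BinnedTrack]) -> VoteTrack:
        return scan_genome(self.forest, tracks)

    def call_enhancers(
        self,
        tracks: list[BinnedTrack],
        cutoff: float = 0.5,
        filter_distance: int = 1000,
    ) -> list[EnhancerCall]:
        return call_peaks(self.scan(tracks), cutoff, filter_distance)

    def summary(self, importance_seed: int = 0) -> str:
        ts = self.model.training_set
        n_pos = int(np.sum(ts.labels == ENHANCER))
        imp = self.importance(seed=importance_seed)
        table = pd.DataFrame(
            {
                "mark": imp.mark_names,
                "importance": np.round(imp.importance, 5),
                "rank": imp.ranks,
            }
        ).sort_values("rank")
        lines = [
            "Vector Random Forest — enhancer classification",
            "=" * 54,
            f"Samples:            {ts.n_samples} ({n_pos} enhancer, {ts.n_samples - n_pos} non-enhancer)",
            f"Marks:              {ts.n_marks} × 20 bins (±1 kb at 100 bp)",
            f"Trees:              {self.forest.n_trees}",
            f"mtry / min_node:    {self.forest.params.get('mtry')} / {self.forest.params.get('min_node')}",
            f"Seed:               {self.forest.seed}",
            f"OOB error:          {self.oob_error_:.4f} ({self.n_oob_excluded_} samples without OOB trees)",
            "",
            "OOB permutation importance (error increase):",
            table.to_string(index=False),
        ]
        return "\n".join(lines)

    def save(self, path: str) -> None:
        save_forest(self.forest, path)

    @classmethod
    def from_file(cls, path: str, training_set: FeatureBlockMatrix | None = None):
        forest = load_forest(path)
        model = EnhancerForest(training_set) if training_set is not None else None
        return cls(model, forest)
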