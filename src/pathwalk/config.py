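"""Run configuration for the full pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

__all__ = ["RunConfig"]

CLASSIFIERS = ("logistic_regression", "svm", "naive_bayes")


@dataclass
class RunConfig:
    """Pipeline settings.

    ``drw_compat`` switches to the binary-class baseline: signed equal-variance
    t-statistic gene weighting and no pathway selection (all pathways kept).
    ``transductive`` computes gene statistics, weights and pathway selection on
    the whole dataset before cross-validation (information-leaking; kept only
    as a comparison mode). Default is fold-safe.
    """

    stat: str = "anova"  # anova | welch | ttest
    r: float = 0.7  # restart probability
    tol: float = 1e-10
    max_iter: int = 10000
    alpha: float = 0.05  # raw per-gene p-value cutoff
    top_n: int = 100  # pathways selected by training |F|
    classifier: str = "logistic_regression"
    folds: int = 10
    repeats: int = 10
    seed: int = 0
    transductive: bool = False
    drw_compat: bool = False

    def __post_init__(self):
        if self.stat not in ("anova", "welch", "ttest"):
            raise ValueError(f"unknown statistic {self.stat!r}")
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if not (0 < self.r <= 1):
            raise ValueError("restart probability must be in (0, 1]")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")

    def resolved(self) -> "RunConfig":
        """Apply drw_compat implications: t-test statistic, no selection."""
        if not self.drw_compat:
            return self
        return replace(self, stat="ttest", top_n=10**9)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)
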