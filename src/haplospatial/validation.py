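"""Self-validation of the fixed-margin randomization test.

A statistical test is only trustworthy if, fed data generated under its own
null hypothesis, it rejects at the nominal rate and produces a rectangular
(uniform) P-value distribution.  This harness repeatedly builds
pseudo-observed tables under the independence null — allocating the template's
N observations to cells with probability proportional to the product of the
template's marginal frequencies — runs the whole-table test on each, and
summarises the rejection rate and P-value histogram.  Pseudo-tables with an
empty row or column are excluded (the chi-squared statistic is undefined
there); they are regenerated so the number of tests stays fixed, and the
exclusion count is reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .contingency import ContingencyMatrix, whole_table_test

__all__ = ["ValidationReport", "generate_pseudo_dataset", "validate"]


@dataclass
class ValidationReport:
    """Outcome of a null-model validation run."""

    n_tests: int
    reps_per_test: int
    alpha: float
    rejection_rate: float
    p_values: np.ndarray
    n_excluded: int
    n_bins: int = 20
    p_histogram: np.ndarray = field(init=False)
    uniformity_statistic: float = field(init=False)

    def __post_init__(self) -> None:
        edges = np.linspace(0.0, 1.0, self.n_bins + 1)
        # P-values live in (0, 1]; put p == 0 (impossible) and p == 1 in bins
        hist, _ = np.histogram(np.clip(self.p_values, 1e-12, 1.0), bins=edges)
        self.p_histogram = hist
        expected = self.n_tests / self.n_bins
        self.uniformity_statistic = float(((hist - expected) ** 2 / expected).sum())

    def rejection_rate_at(self, alpha: float) -> float:
        return float((self.p_values <= alpha).mean())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "n_tests": self.n_tests,
                "reps_per_test": self.reps_per_test,
                "alpha": self.alpha,
                "rejection_rate": self.rejection_rate,
                "n_excluded": self.n_excluded,
                "p_histogram": self.p_histogram.tolist(),
                "uniformity_statistic": self.uniformity_statistic,
            }, fh, indent=2)

    def plot_histogram(self, path) -> None:
        """Write the P-value histogram; a calibrated test gives a flat bar chart."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        edges = np.linspace(0.0, 1.0, self.n_bins + 1)
        ax.bar(edges[:-1], self.p_histogram, width=np.diff(edges),
               align="edge", edgecolor="black", color="#7aa6c2")
        ax.axhline(self.n_tests / self.n_bins, ls="--", color="red",
                   label="uniform expectation")
        ax.set_xlabel("P-value")
        ax.set_ylabel("count")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def generate_pseudo_dataset(template: ContingencyMatrix,
                            rng: np.random.Generator,
                            allocation: str = "margins",
                            max_attempts: int = 10_000,
                            ) -> tuple[ContingencyMatrix, int]:
    """One pseudo-observed table under the independence null.

    The template's N observations are dropped independently into cells with
    probability r_i * c_j / N^2 (``allocation='margins'``: expected margins
    match the template) or uniformly over cells (``allocation='uniform'``).
    Realisations with an empty row or column are discarded and redrawn; the
    second return value counts the discards.
    """
    if allocation == "margins":
        p = np.outer(template.row_totals, template.col_totals).astype(float)
    elif allocation == "uniform":
        p = np.ones(template.shape)
    else:
        raise ValueError(f"unknown allocation {allocation!r}")
    p = (p / p.sum()).ravel()
    n = template.n
    excluded = 0
    for _ in range(max_attempts):
        counts = rng.multinomial(n, p).reshape(template.shape)
        if (counts.sum(axis=1) > 0).all() and (counts.sum(axis=0) > 0).all():
            return (ContingencyMatrix(counts, template.row_labels,
                                      template.col_labels), excluded)
        excluded += 1
    raise RuntimeError("could not draw a pseudo-table without empty margins; "
                       "the template is too sparse")


def validate(template: ContingencyMatrix, n_tests: int = 10_000,
             reps_per_test: int = 10_000, alpha: float = 0.05,
             seed: int | None = None,
             allocation: str = "margins") -> ValidationReport:
    """Run ``n_tests`` null analyses and summarise test calibration.

    Each pseudo-dataset gets a whole-table randomization test with
    ``reps_per_test`` fixed-margin tables; the report carries all P-values,
    the rejection rate at ``alpha``, a histogram, and a chi-squared
    goodness-of-fit statistic for rectangularity.
    """
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    rng = np.random.default_rng(seed)
    p_values = np.empty(n_tests)
    n_excluded = 0
    for t in range(n_tests):
        pseudo, excl = generate_pseudo_dataset(template, rng, allocation)
        n_excluded += excl
        # independent child seed per test keeps runs reproducible
        child = int(rng.integers(2 ** 31))
        _, p_values[t] = whole_table_test(pseudo, m=reps_per_test, seed=child)
    rate = float((p_values <= alpha).mean())
    return ValidationReport(n_tests=n_tests, reps_per_test=reps_per_test,
                            alpha=alpha, rejection_rate=rate,
                            p_values=p_values, n_excluded=n_excluded)
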