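"""In-vivo repeat-addition processivity from consecutive-repeat run lengths.

Telomerase either adds another hexamer processively (probability ``P(x)``)
or dissociates (``1 − P(x)``). In a cell carrying both a wild-type and a
variant TERC template, a dissociated enzyme is replaced by one carrying
the variant template with probability ``rho`` (0.5 under equal expression
of the two alleles). The chance that the next deposited repeat matches the
current one is therefore

    P(Add) = P(x) + (1 − P(x)) · rho

and maximal runs of same-class repeats are geometric with continuation
probability P(Add): the survival fraction of runs of length ≥ x is
S(x) = P(Add)^(x−1), so log2 S(x) is linear in x with slope log2 P(Add).
Fitting that line to an observed run-length survival curve and inverting

    P(x) = (2^slope − rho) / (1 − rho)

recovers the in-vivo repeat-addition processivity of each allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
from scipy import stats

from .composition import DetectionConfig, RunLengthTable, run_lengths
from .records import ReadRecord

__all__ = [
    "EstimationError",
    "SurvivalCurve",
    "ProcessivityEstimate",
    "ProcessivityResult",
    "forward_p_add",
    "model_run_survival",
    "survival_from_runs",
    "fit_processivity",
    "estimate_from_table",
    "estimate_from_reads",
    "plot_survival",
]


class EstimationError(RuntimeError):
    """A processivity estimate could not be produced from the data."""


def _check_probability(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


def forward_p_add(p_x: float, rho: float) -> float:
    """Probability of consecutive same-class addition, P(Add).

    ``p_x`` is the processive-continuation probability; with probability
    ``1 − p_x`` the enzyme dissociates and a re-associating enzyme carries
    the same template with probability ``rho``. The two routes are mutually
    exclusive, hence ``P(Add) = p_x + (1 − p_x) · rho``.
    """
    _check_probability("p_x", p_x)
    _check_probability("rho", rho)
    return p_x + (1.0 - p_x) * rho


def model_run_survival(p_x: float, rho: float, x: int) -> float:
    """Model probability that a run reaches length >= x: P(Add)^(x-1)."""
    if x < 1:
        raise ValueError("run length x must be >= 1")
    return forward_p_add(p_x, rho) ** (x - 1)


@dataclass
class SurvivalCurve:
    """Run-length survival curve for one repeat class.

    ``points`` are ``(x, S, n_runs_at_least_x)`` triples with
    ``S(x) = #runs of length >= x / #runs`` (or, with
    ``weighting="repeats"``, the fraction of repeats that sit in runs of
    length >= x). S(1) is 1 by construction and S is non-increasing.
    """

    repeat_class: str
    points: List[Tuple[int, float, int]]
    total_runs: int
    weighting: str = "runs"

    @property
    def x(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def survival(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)


def survival_from_runs(
    table: RunLengthTable,
    repeat_class: str,
    min_runs: int = 5,
    weighting: str = "runs",
) -> SurvivalCurve:
    """Build the run-length survival curve for one repeat class.

    Points are included for x = 1 up to the largest x whose cumulative run
    count is still at least ``min_runs``, so the log-scale tail is not
    dominated by a handful of runs. ``weighting="repeats"`` weights each
    run by its length (sensitivity analysis; the default run weighting is
    the one under which log2 S is exactly linear for a geometric process).
    """
    if weighting not in ("runs", "repeats"):
        raise ValueError("weighting must be 'runs' or 'repeats'")
    counts = table.runs[repeat_class]
    total_runs = sum(counts.values())
    if total_runs == 0:
        raise EstimationError(f"no runs for repeat class {repeat_class!r}")
    max_len = max(counts)
    total_repeats = table.total_repeats(repeat_class)
    points: List[Tuple[int, float, int]] = []
    n_ge = total_runs
    repeats_ge = total_repeats
    for x in range(1, max_len + 1):
        if n_ge < min_runs and x > 1:
            break
        s = repeats_ge / total_repeats if weighting == "repeats" else n_ge / total_runs
        points.append((x, s, n_ge))
        n_ge -= counts.get(x, 0)
        repeats_ge -= x * counts.get(x, 0)
    return SurvivalCurve(repeat_class, points, total_runs, weighting)


@dataclass
class ProcessivityEstimate:
    """A fitted processivity value for one repeat class, with diagnostics.

    ``p_add = 2**slope`` and ``p_x = (p_add − rho_used)/(1 − rho_used)``;
    both relations hold for the raw values before clamping. ``p_x`` is
    reported clamped to [0, 1] with ``clamped`` set if the raw value fell
    outside (the model cannot represent anti-processivity).
    """

    repeat_class: str
    slope: float
    intercept: float
    p_add: float
    p_x: float
    rho_used: float
    n_points_fit: int
    r_squared: float
    clamped: bool = False
    p_x_raw: float = field(default=float("nan"), repr=False)

    def as_dict(self) -> Dict[str, object]:
        return {
            "repeat_class": self.repeat_class,
            "slope": self.slope,
            "intercept": self.intercept,
            "p_add": self.p_add,
            "p_x": self.p_x,
            "rho_used": self.rho_used,
            "n_points_fit": self.n_points_fit,
            "r_squared": self.r_squared,
            "clamped": self.clamped,
        }


def fit_processivity(
    curve: SurvivalCurve, rho: float = 0.5, include_s1: bool = True
) -> ProcessivityEstimate:
    """Fit log2 S(x) ~ x by OLS and back-calculate P(x).

    ``rho`` is the re-association probability toward this curve's allele
    and must lie in [0, 1). ``include_s1`` keeps the (1, 0) anchor point in
    the regression (the default; it is exact for any geometric curve).
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho must lie in [0, 1), got {rho!r}")
    pts = [(x, s) for x, s, _ in curve.points if s > 0]
    if not include_s1:
        pts = [(x, s) for x, s in pts if x > 1]
    if len(pts) < 2:
        raise EstimationError(
            f"insufficient run-length range for {curve.repeat_class!r}: "
            f"{len(pts)} usable point(s), need >= 2"
        )
    xs = np.array([x for x, _ in pts], dtype=float)
    ys = np.log2([s for _, s in pts])
    if np.allclose(ys, ys[0]):
        # constant survival (fully processive limit): slope 0 exactly
        slope, intercept, r2 = 0.0, float(ys[0]), float("nan")
    else:
        fit = stats.linregress(xs, ys)
        slope, intercept, r2 = float(fit.slope), float(fit.intercept), float(fit.rvalue**2)
    p_add = 2.0**slope
    p_x_raw = (p_add - rho) / (1.0 - rho)
    p_x = min(1.0, max(0.0, p_x_raw))
    return ProcessivityEstimate(
        repeat_class=curve.repeat_class,
        slope=slope,
        intercept=intercept,
        p_add=p_add,
        p_x=p_x,
        rho_used=rho,
        n_points_fit=len(pts),
        r_squared=r2,
        clamped=p_x != p_x_raw,
        p_x_raw=p_x_raw,
    )


@dataclass
class ProcessivityResult:
    """Per-class estimates plus reasons for any class that failed."""

    estimates: Dict[str, ProcessivityEstimate] = field(default_factory=dict)
    failures: Dict[str, str] = field(default_factory=dict)
    curves: Dict[str, SurvivalCurve] = field(default_factory=dict)


def estimate_from_table(
    table: RunLengthTable,
    rho: float = 0.5,
    min_runs: int = 5,
    weighting: str = "runs",
    include_s1: bool = True,
) -> ProcessivityResult:
    """Estimate P(x) for both repeat classes from a run-length table.

    The variant allele uses re-association probability ``rho``; the
    wild-type allele uses ``1 − rho`` (a dissociated enzyme re-associates
    with the wild-type template with the complementary probability).
    """
    result = ProcessivityResult()
    for repeat_class, rho_used in (("wt", 1.0 - rho), ("var", rho)):
        try:
            curve = survival_from_runs(table, repeat_class, min_runs, weighting)
            result.curves[repeat_class] = curve
            result.estimates[repeat_class] = fit_processivity(curve, rho_used, include_s1)
        except EstimationError as exc:
            result.failures[repeat_class] = str(exc)
    return result


def estimate_from_reads(
    reads: Iterable[ReadRecord],
    config: DetectionConfig = DetectionConfig(),
    rho: float = 0.5,
    min_runs: int = 5,
) -> ProcessivityResult:
    """Run detection → trim → orient → run lengths → survival fit.

    Convenience composition of :func:`telovar.composition.run_lengths` and
    :func:`estimate_from_table` for a raw read stream.
    """
    table = run_lengths(reads, config)
    return estimate_from_table(table, rho=rho, min_runs=min_runs)


def plot_survival(
    curves: Iterable[SurvivalCurve],
    path: Optional[str] = None,
    estimates: Optional[Dict[str, ProcessivityEstimate]] = None,
):
    """Plot log2 run-length survival curves (and fitted lines, if given)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"wt": "tab:blue", "var": "tab:orange"}
    for curve in curves:
        color = colors.get(curve.repeat_class)
        ax.plot(
            curve.x,
            np.log2(curve.survival),
            "o",
            color=color,
            label=f"{curve.repeat_class} (n={curve.total_runs} runs)",
        )
        if estimates and curve.repeat_class in estimates:
            est = estimates[curve.repeat_class]
            ax.plot(curve.x, est.intercept + est.slope * curve.x, "-", color=color)
    ax.set_xlabel("consecutive repeats x")
    ax.set_ylabel("log2 S(x)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
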