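"""Fitting the tactoid shape-scaling law R/r = C * V**(-1/5) to populations.

Measured tactoid populations (one per phage species or condition) are fitted
in log space, where the law is linear and the multiplicative scatter of real
aspect ratios becomes additive:

    log(R/r) = log C + exponent * log V + eps,   eps ~ N(0, sigma_log**2)

Two estimators are provided through a statsmodels-style Model/Results pair:
with the exponent fixed at the theoretical -1/5 the fit is a one-parameter
location estimate of log C; with the exponent free it is an ordinary
least-squares regression of log aspect ratio on log volume, which serves as
a check that the data actually follow the predicted power law.  Prefactors
of two species are compared with :func:`prefactor_ratio`, whose standard
error is propagated from the two log-space errors by the delta method, and
optionally by case-resampling bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .theory import TactoidShape

__all__ = [
    "TactoidPopulation",
    "ScalingLawModel",
    "ScalingLawResults",
    "ScalingFitResult",
    "fit_prefactor",
    "fit_free_exponent",
    "bootstrap_prefactor_ci",
    "prefactor_ratio",
]

THEORY_EXPONENT = -0.2  # aspect ratio ~ V**(-1/5) for elongated nematic droplets


@dataclass(frozen=True)
class TactoidPopulation:
    """A labelled population of measured tactoids with volumes.

    ``aspect_ratios`` and ``volumes`` are parallel arrays; records are built
    from :class:`~tactoidlab.theory.TactoidShape` objects or a DataFrame.
    Aspect ratios below 1 are rejected rather than inverted so that
    axis-ordering mistakes in upstream tables surface loudly.
    """

    volumes: np.ndarray
    aspect_ratios: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.volumes, dtype=float)
        ar = np.asarray(self.aspect_ratios, dtype=float)
        object.__setattr__(self, "volumes", v)
        object.__setattr__(self, "aspect_ratios", ar)
        if v.shape != ar.shape or v.ndim != 1 or v.size == 0:
            raise ValueError("volumes and aspect_ratios must be equal-length 1-D, non-empty")
        bad_v = np.nonzero(~(v > 0))[0]
        if bad_v.size:
            raise ValueError(f"non-positive volumes at records {bad_v.tolist()}")
        bad_ar = np.nonzero(~(ar >= 1))[0]
        if bad_ar.size:
            raise ValueError(
                f"aspect ratios < 1 at records {bad_ar.tolist()}; "
                "check major/minor axis ordering"
            )

    @classmethod
    def from_shapes(cls, shapes: list[TactoidShape], label: str = "") -> "TactoidPopulation":
        vols = []
        for s in shapes:
            if s.volume is None:
                raise ValueError("every TactoidShape needs a volume")
            vols.append(s.volume)
        return cls(
            volumes=np.array(vols),
            aspect_ratios=np.array([s.aspect_ratio for s in shapes]),
            label=label,
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label: str = "") -> "TactoidPopulation":
        """Build from a table with ``major_um``, ``minor_um`` and either
        ``volume_um3`` or axes from which a prolate-spheroid volume is derived."""
        if "volume_um3" in df.columns:
            vols = df["volume_um3"].to_numpy(float)
        else:
            from .morphometry import spheroid_volume_from_axes

            vols = spheroid_volume_from_axes(
                df["major_um"].to_numpy(float), df["minor_um"].to_numpy(float)
            )
        ar = df["major_um"].to_numpy(float) / df["minor_um"].to_numpy(float)
        if not label and "label" in df.columns and len(df):
            label = str(df["label"].iloc[0])
        return cls(volumes=vols, aspect_ratios=ar, label=label)

    def __len__(self) -> int:
        return self.volumes.size


class ScalingLawModel:
    """Power-law model R/r = C * V**exponent for a tactoid population.

    Parameters
    ----------
    population
        The measured tactoids.
    exponent
        Fixed exponent (default the theoretical -1/5), or ``None`` to
        estimate it by OLS in log space (requires >= 2 distinct volumes).
    """

    def __init__(self, population: TactoidPopulation, exponent: float | None = THEORY_EXPONENT):
        self.population = population
        self.exponent = exponent

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, exponent: float | None = THEORY_EXPONENT, label: str = ""
    ) -> "ScalingLawModel":
        return cls(TactoidPopulation.from_dataframe(df, label=label), exponent=exponent)

    def fit(self) -> "ScalingLawResults":
        pop = self.population
        log_v = np.log(pop.volumes)
        log_ar = np.log(pop.aspect_ratios)
        n = len(pop)

        if self.exponent is not None:
            # One-parameter location fit: log C = mean(log(R/r) - exponent*log V)
            z = log_ar - self.exponent * log_v
            log_c = float(np.mean(z))
            resid = z - log_c
            # ddof=1 residual SD; a single point fits exactly with sd 0
            resid_sd = float(np.sqrt(np.sum(resid**2) / (n - 1))) if n > 1 else 0.0
            log_c_se = resid_sd / math.sqrt(n)
            return ScalingLawResults(
                model=self,
                prefactor=math.exp(log_c),
                log_prefactor=log_c,
                log_prefactor_se=log_c_se,
                exponent=self.exponent,
                exponent_se=None,
                n_points=n,
                residual_sd=resid_sd,
            )

        if np.unique(pop.volumes).size < 2:
            raise ValueError("free-exponent fit needs >= 2 distinct volumes")
        import statsmodels.api as sm

        ols = sm.OLS(log_ar, sm.add_constant(log_v)).fit()
        log_c, slope = ols.params
        resid_sd = float(np.sqrt(ols.scale)) if n > 2 else 0.0
        return ScalingLawResults(
            model=self,
            prefactor=math.exp(float(log_c)),
            log_prefactor=float(log_c),
            log_prefactor_se=float(ols.bse[0]),
            exponent=float(slope),
            exponent_se=float(ols.bse[1]),
            n_points=n,
            residual_sd=resid_sd,
        )


@dataclass(frozen=True)
class ScalingLawResults:
    """Fitted scaling law: prefactor C (units volume**(-exponent), i.e.
    um**(3/5) at the theoretical exponent), its log-space standard error,
    the exponent (with SE when estimated), and the log-space residual SD."""

    model: ScalingLawModel
    prefactor: float
    log_prefactor: float
    log_prefactor_se: float
    exponent: float
    exponent_se: float | None
    n_points: int
    residual_sd: float

    @property
    def prefactor_se(self) -> float:
        """Delta-method SE of C: C * se(log C)."""
        return self.prefactor * self.log_prefactor_se

    @property
    def exponent_fixed(self) -> bool:
        return self.exponent_se is None

    def bootstrap_prefactor_ci(
        self, n_boot: int = 1000, seed: int | None = None, level: float = 0.95
    ) -> tuple[float, float]:
        """Case-resampling percentile interval for the prefactor C.

        Records are resampled with replacement ``n_boot`` times (>= 100) and
        the model refitted on each; reproducible given ``seed``.
        """
        if n_boot < 100:
            raise ValueError("n_boot must be >= 100")
        pop = self.model.population
        n = len(pop)
        if n < 2:
            raise ValueError("bootstrap needs a population of >= 2 records")
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n, size=(n_boot, n))
        log_v = np.log(pop.volumes)
        log_ar = np.log(pop.aspect_ratios)
        if self.exponent_fixed:
            z = log_ar - self.exponent * log_v
            boot_log_c = np.mean(z[idx], axis=1)
        else:
            boot_log_c = np.empty(n_boot)
            for i in range(n_boot):
                sub = TactoidPopulation(pop.volumes[idx[i]], pop.aspect_ratios[idx[i]])
                boot_log_c[i] = ScalingLawModel(sub, exponent=None).fit().log_prefactor
        alpha = 1.0 - level
        lo, hi = np.quantile(np.exp(boot_log_c), [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)

    def summary(self) -> str:
        lines = [
            "Tactoid scaling-law fit: R/r = C * V**exponent",
            f"  population: {self.model.population.label or '<unlabelled>'}"
            f"  (n = {self.n_points})",
            f"  C          = {self.prefactor:.4g} +/- {self.prefactor_se:.2g}",
            f"  exponent   = {self.exponent:.4g}"
            + (" (fixed)" if self.exponent_fixed else f" +/- {self.exponent_se:.2g}"),
            f"  residual SD (log space) = {self.residual_sd:.4g}",
        ]
        return "\n".join(lines)


# Legacy-style alias used in tabular outputs
ScalingFitResult = ScalingLawResults


def fit_prefactor(
    pop: TactoidPopulation, exponent: float = THEORY_EXPONENT
) -> ScalingLawResults:
    """Fixed-exponent log-space fit of the prefactor C (see ScalingLawModel)."""
    return ScalingLawModel(pop, exponent=exponent).fit()


def fit_free_exponent(pop: TactoidPopulation) -> ScalingLawResults:
    """OLS of log(R/r) on log V: estimates both exponent and prefactor."""
    return ScalingLawModel(pop, exponent=None).fit()


def bootstrap_prefactor_ci(
    pop: TactoidPopulation,
    n_boot: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    exponent: float = THEORY_EXPONENT,
) -> tuple[float, float]:
    """Percentile bootstrap interval for the fixed-exponent prefactor."""
    return fit_prefactor(pop, exponent=exponent).bootstrap_prefactor_ci(
        n_boot=n_boot, seed=seed, level=level
    )


def prefactor_ratio(
    fit_a: ScalingLawResults, fit_b: ScalingLawResults
) -> tuple[float, float]:
    """Ratio C_A/C_B of two fitted prefactors with delta-method SE.

    Both fits must share the same fixed exponent; comparing fits with free
    (and hence different) exponents would confound prefactor and slope.
    """
    if not (fit_a.exponent_fixed and fit_b.exponent_fixed):
        raise ValueError("prefactor_ratio requires fixed-exponent fits")
    if fit_a.exponent != fit_b.exponent:
        raise ValueError(
            f"mismatched exponents: {fit_a.exponent} vs {fit_b.exponent}"
        )
    ratio = fit_a.prefactor / fit_b.prefactor
    se = ratio * math.hypot(fit_a.log_prefactor_se, fit_b.log_prefactor_se)
    return ratio, se
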