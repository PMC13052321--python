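"""Virtual population and concentration-time simulation.

A small proof-of-concept study population: 10 female and 10 male adults with
sex-specific weight/height distributions, dosed once with 300 mg of a
hypothetical drug following a one-compartment model with first-order
absorption and linear elimination.  Inter-individual variability is
log-normal on ka, V and Cl; weight enters the volume of distribution
allometrically; residual error is combined additive + proportional;
observations below the lower limit of quantification (LLOQ) are censored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NOMINAL_TIMES",
    "PopulationSpec",
    "GroundTruthParameters",
    "sample_covariates",
    "individual_parameters",
    "concentration",
    "simulate_observations",
    "censor_blq",
    "to_nonmem",
    "simulate_dataset",
]

#: Nominal sampling times (hours post-dose).
NOMINAL_TIMES: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 12.0)

#: Column order of the NONMEM-style long-format dataset.
NONMEM_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "SEX", "AGE", "WT", "HT", "SRC"]


@dataclass
class PopulationSpec:
    """Covariate distributions of the virtual study population.

    Ages are uniform on ``[age_low, age_high]`` years; weight (kg) and height
    (cm) are normal with sex-specific means and a shared SD.
    """

    n_female: int = 10
    n_male: int = 10
    age_low: float = 18.0
    age_high: float = 65.0
    weight_mean_f: float = 64.0
    weight_mean_m: float = 85.0
    weight_sd: float = 10.0
    height_mean_f: float = 164.0
    height_mean_m: float = 179.0
    height_sd: float = 7.0

    def __post_init__(self) -> None:
        if self.n_female < 0 or self.n_male < 0:
            raise ValueError("patient counts must be non-negative")
        if not self.age_low < self.age_high:
            raise ValueError("age_low must be < age_high")
        if self.weight_sd <= 0 or self.height_sd <= 0:
            raise ValueError("covariate SDs must be positive")


@dataclass
class GroundTruthParameters:
    """Population PK parameters driving the simulation.

    ``ka_pop`` (1/h), ``v_pop`` (L) and ``cl_pop`` (L/h) are the typical
    values; ``beta_wt_v`` is the allometric exponent of weight (normalised by
    ``w_ref`` kg) on V; the omegas are the SDs of log-scale random effects;
    residual error SD is ``a + b*C`` (``a`` in mg/L, ``b`` dimensionless).
    """

    ka_pop: float = 0.5
    v_pop: float = 14.0
    cl_pop: float = 5.0
    beta_wt_v: float = 0.75
    omega_ka: float = 0.2
    omega_v: float = 0.3
    omega_cl: float = 0.2
    a: float = 0.2
    b: float = 0.1
    w_ref: float = 70.0
    dose: float = 300.0
    lloq: float = 0.5

    def __post_init__(self) -> None:
        for name in ("ka_pop", "v_pop", "cl_pop", "w_ref", "dose", "lloq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("omega_ka", "omega_v", "omega_cl", "a", "b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def sample_covariates(spec: PopulationSpec, seed: int) -> pd.DataFrame:
    """Draw patient covariates.

    Returns a frame with columns ``id, sex, age, weight, height``; females
    first, ids starting at 1.  Non-positive normal draws for weight/height are
    redrawn (vanishingly rare at the default means).
    """
    rng = np.random.default_rng(seed)
    rows = []
    pid = 1
    for sex, n, wm, hm in (
        ("female", spec.n_female, spec.weight_mean_f, spec.height_mean_f),
        ("male", spec.n_male, spec.weight_mean_m, spec.height_mean_m),
    ):
        age = rng.uniform(spec.age_low, spec.age_high, size=n)
        weight = _positive_normal(rng, wm, spec.weight_sd, n)
        height = _positive_normal(rng, hm, spec.height_sd, n)
        for i in range(n):
            rows.append((pid, sex, age[i], weight[i], height[i]))
            pid += 1
    return pd.DataFrame(rows, columns=["id", "sex", "age", "weight", "height"])


def _positive_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    x = rng.normal(mean, sd, size=n)
    while np.any(x <= 0):
        bad = x <= 0
        x[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return x


def individual_parameters(
    theta: GroundTruthParameters, covariates: pd.DataFrame, seed: int
) -> pd.DataFrame:
    """Draw individual PK parameters.

    ka_i = ka_pop * exp(eta_ka);  Cl_i = cl_pop * exp(eta_cl);
    V_i = v_pop * (weight / w_ref)**beta_wt_v * exp(eta_v);
    with independent eta ~ N(0, omega^2) per patient and parameter.
    """
    rng = np.random.default_rng(seed)
    n = len(covariates)
    eta = rng.normal(size=(n, 3)) * np.array([theta.omega_ka, theta.omega_v, theta.omega_cl])
    weight = covariates["weight"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "id": covariates["id"].to_numpy(),
            "ka_i": theta.ka_pop * np.exp(eta[:, 0]),
            "v_i": theta.v_pop * (weight / theta.w_ref) ** theta.beta_wt_v * np.exp(eta[:, 1]),
            "cl_i": theta.cl_pop * np.exp(eta[:, 2]),
        }
    )


def concentration(ka, v, cl, dose, t):
    """Closed-form one-compartment concentration after a single oral dose.

    C(t) = dose*ka / (V*(ka-ke)) * (exp(-ke t) - exp(-ka t)),  ke = Cl/V,
    with bioavailability fixed at 1 (V and Cl are apparent values).  Computed
    in the cancellation-free form  dose*ka/V * exp(-ke t) * phi((ka-ke) t) * t
    with phi(x) = (1-exp(-x))/x, so the ka -> ke limit is exact; ``phi`` is
    evaluated by series for small |x|, which keeps the expression analytic and
    therefore safe for complex-step differentiation.

    Broadcasts over numpy arrays; supports complex dtype.
    """
    ka = np.asarray(ka)
    v = np.asarray(v)
    cl = np.asarray(cl)
    t = np.asarray(t)
    if not (np.all(np.isfinite(ka)) and np.all(np.isfinite(v)) and np.all(np.isfinite(cl))):
        raise FloatingPointError("non-finite PK parameters")
    return _concentration_unchecked(ka, v, cl, dose, t)


def _concentration_unchecked(ka, v, cl, dose, t):
    """Hot-path variant of :func:`concentration` without input validation.

    Evaluates C = dose*ka/V * t * exp(-k_slow t) * phi(|ka-ke| t) with the
    slower of the two rate constants in the exponential, so no intermediate
    overflows regardless of which of ka, ke dominates.
    """
    ke = cl / v
    x = (ka - ke) * t
    swap = np.real(x) < 0
    krate = np.where(swap, ka, ke)
    xs = np.where(swap, -x, x)
    return dose * ka / v * np.exp(-krate * t) * t * _phi(xs)


def _phi(x):
    """(1 - exp(-x)) / x, analytic continuation at 0; complex-safe."""
    x = np.asarray(x)
    ax = np.abs(x)
    if np.all(ax >= 1e-4):  # common case: ka and ke well separated
        if np.iscomplexobj(x):
            return (1.0 - np.exp(-x)) / x
        return -np.expm1(-x) / x
    small = ax < 1e-4
    xs = np.where(small, 1.0, x)
    if np.iscomplexobj(x):
        # np.expm1 has no complex support; plain exp is fine away from 0
        big = (1.0 - np.exp(-xs)) / xs
    else:
        big = -np.expm1(-xs) / xs
    series = 1.0 - x / 2.0 + x**2 / 6.0 - x**3 / 24.0
    return np.where(small, series, big)


def simulate_observations(
    theta: GroundTruthParameters,
    covariates: pd.DataFrame,
    times=NOMINAL_TIMES,
    seed: int = 0,
    individual: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Simulate observed concentrations for every patient and time.

    y = C + (a + b*C)*eps with eps ~ N(0,1); negative draws are floored at 0;
    the ``blq`` flag marks observations below ``theta.lloq``.  Individual
    parameters are drawn internally (sub-seed ``seed``; noise uses
    ``seed + 1``) unless ``individual`` is supplied.
    """
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing and positive")
    if individual is None:
        individual = individual_parameters(theta, covariates, seed)
    rng = np.random.default_rng(seed + 1)
    ka = individual["ka_i"].to_numpy()[:, None]
    v = individual["v_i"].to_numpy()[:, None]
    cl = individual["cl_i"].to_numpy()[:, None]
    c = concentration(ka, v, cl, theta.dose, times[None, :])
    eps = rng.normal(size=c.shape)
    y = c + (theta.a + theta.b * c) * eps
    y = np.maximum(y, 0.0)
    n = len(individual)
    return pd.DataFrame(
        {
            "id": np.repeat(individual["id"].to_numpy(), len(times)),
            "time": np.tile(times, n),
            "conc": y.ravel(),
            "blq": (y < theta.lloq).ravel(),
        }
    )


def censor_blq(obs: pd.DataFrame, lloq: float, mode: str = "drop") -> pd.DataFrame:
    """Censor observations below the LLOQ.

    ``mode='drop'`` removes them (as done before PopPK fitting); ``mode='flag'``
    keeps all rows with the ``blq`` column set.
    """
    if lloq <= 0:
        raise ValueError("lloq must be positive")
    out = obs.copy()
    out["blq"] = out["conc"] < lloq
    if mode == "drop":
        return out.loc[~out["blq"]].reset_index(drop=True)
    if mode == "flag":
        return out
    raise ValueError(f"unknown mode {mode!r}")


def to_nonmem(
    covariates: pd.DataFrame,
    observations: pd.DataFrame,
    dose: float,
    src: str = "original",
) -> pd.DataFrame:
    """Assemble the NONMEM-style long dataset.

    One dose row per patient (EVID=1, AMT=dose, TIME=0, MDV=1) followed by the
    observation rows (EVID=0, MDV=0).  SEX is coded 0=female, 1=male.
    """
    cov = covariates.set_index("id")
    frames = []
    for pid, sub in observations.groupby("id", sort=True):
        c = cov.loc[pid]
        sex = 1 if c["sex"] == "male" else 0
        base = {"ID": pid, "SEX": sex, "AGE": c["age"], "WT": c["weight"], "HT": c["height"], "SRC": src}
        rows = [{**base, "TIME": 0.0, "AMT": dose, "DV": 0.0, "EVID": 1, "MDV": 1}]
        for _, r in sub.sort_values("time").iterrows():
            rows.append({**base, "TIME": r["time"], "AMT": 0.0, "DV": r["conc"], "EVID": 0, "MDV": 0})
        frames.append(pd.DataFrame(rows))
    if not frames:
        return pd.DataFrame(columns=NONMEM_COLUMNS)
    return pd.concat(frames, ignore_index=True)[NONMEM_COLUMNS]


def simulate_dataset(
    theta: GroundTruthParameters | None = None,
    spec: PopulationSpec | None = None,
    seed: int = 0,
    times=NOMINAL_TIMES,
    blq: str = "drop",
    src: str = "original",
):
    """Convenience wrapper: covariates -> observations -> long dataset.

    Returns ``(covariates, observations, long_df)``; ``long_df`` has BLQ rows
    handled per ``blq`` ('drop', 'flag' or 'keep').
    """
    theta = theta or GroundTruthParameters()
    spec = spec or PopulationSpec()
    cov = sample_covariates(spec, seed)
    obs = simulate_observations(theta, cov, times=times, seed=seed + 1000)
    if blq in ("drop", "flag"):
        exported = censor_blq(obs, theta.lloq, mode="drop") if blq == "drop" else obs
    elif blq == "keep":
        exported = obs
    else:
        raise ValueError(f"unknown blq mode {blq!r}")
    long_df = to_nonmem(cov, exported, theta.dose, src=src)
    return cov, obs, long_df
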