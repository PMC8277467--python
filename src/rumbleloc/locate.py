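"""Multilateration of a vocalizing source from TDOA sets.

Each TDOA between a reference station p0 and another station pi constrains
the source to a hyperbola: v * (ti - t0) = ||x - pi|| - ||x - p0||.  With
four stations (three independent TDOAs) the hyperbolas intersect in a
single point for the correct wavespeed.  Two solvers are provided:

* deterministic -- for each wavespeed on a grid of guesses, nonlinear least
  squares over the source position (multi-start, since hyperbola
  intersections are non-convex); the grid point with the smallest residual
  wins.
* probabilistic -- an affine-invariant ensemble MCMC posterior over
  position and wavespeed jointly, with a Gaussian likelihood on the
  observed TDOAs.  The joint (bimodal) variant shares one position between
  a seismic and an acoustic TDOA set while estimating a separate wavespeed
  for each medium.

The accuracy proxy for every candidate solution is the residual: the mean
absolute mismatch between observed and predicted TDOAs, expressed in metres
through the wavespeed estimate, so solutions from different methods and
modalities are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import emcee
import numpy as np
from scipy import optimize

from .geometry import StationGeometry, array_bounding_box, station_array
from .tdoa import TdoaSet

__all__ = [
    "SolverConfig",
    "LocationEstimate",
    "PosteriorSamples",
    "TdoaLocationModel",
    "JointTdoaLocationModel",
    "DeterministicResults",
    "ProbabilisticResults",
    "predict_tdoas",
    "compute_residual",
    "best_estimate",
    "localize_deterministic",
    "localize_probabilistic",
    "localize_joint",
]

_DEFAULT_GRIDS = {
    "acoustic": tuple(np.arange(320.0, 380.0 + 1e-9, 5.0)),
    "seismic": tuple(np.arange(200.0, 1500.0 + 1e-9, 25.0)),
}
_DEFAULT_V_PRIORS = {"acoustic": (300.0, 400.0), "seismic": (150.0, 1600.0)}


@dataclass
class SolverConfig:
    """Solver settings shared by the deterministic and probabilistic paths.

    tdoa_sigma defaults to one spectrogram time bin (0.05 s with the default
    STFT settings): lag quantization is the dominant known error source.
    The position prior is a uniform box, by default the station bounding box
    padded by 200 m.
    """

    wavespeed_grid: dict = field(default_factory=lambda: dict(_DEFAULT_GRIDS))
    tdoa_sigma: float = 0.05
    position_prior: tuple[float, float, float, float] | None = None
    wavespeed_prior: dict = field(default_factory=lambda: dict(_DEFAULT_V_PRIORS))
    n_samples: int = 4000
    n_walkers: int = 32
    n_burn: int = 200
    rng_seed: int = 0

    def prior_box(self, stations: list[StationGeometry]) -> tuple[float, float, float, float]:
        return self.position_prior or array_bounding_box(stations, pad=200.0)


@dataclass
class LocationEstimate:
    """One candidate source location with its wavespeed(s) and residual.

    For the joint method ``v`` is the seismic wavespeed and ``v_acoustic``
    the acoustic one; unimodal estimates leave ``v_acoustic`` unset.
    """

    x: np.ndarray
    v: float
    residual: float
    method: str  # det | prob | joint
    modality: str  # seismic | acoustic | both
    v_acoustic: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.v <= 0:
            raise ValueError("wavespeed must be > 0")
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


@dataclass
class PosteriorSamples:
    """Flattened post-burn-in MCMC samples with their log posterior densities."""

    samples: np.ndarray  # (n, 3) = (x, y, v) or (n, 4) = (x, y, v_seis, v_acou)
    log_densities: np.ndarray
    param_names: tuple[str, ...]
    rng_seed: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.log_densities = np.asarray(self.log_densities, dtype=float)
        if self.samples.size == 0:
            raise ValueError("posterior sample set is empty")
        if not np.all(np.isfinite(self.log_densities)):
            raise ValueError("non-finite log densities in posterior sample set")

    @property
    def positions(self) -> np.ndarray:
        return self.samples[:, :2]

    @property
    def map_index(self) -> int:
        return int(np.argmax(self.log_densities))


# ---------------------------------------------------------------------------
# forward model and residual


def predict_tdoas(
    x: np.ndarray,
    stations: list[StationGeometry],
    reference: str,
    v: float,
    order: list[str] | None = None,
) -> np.ndarray:
    """Geometric TDOAs (ti - t0) of a source at ``x`` for wavespeed ``v``.

    lag_i = (||x - p_i|| - ||x - p_0||) / v for every non-reference station,
    in ``order`` (default: station list order).
    """
    if v <= 0:
        raise ValueError("wavespeed must be > 0")
    by_id = {s.station_id: s for s in stations}
    if reference not in by_id:
        raise ValueError(f"reference {reference!r} not among stations")
    ids = order if order is not None else [s.station_id for s in stations if s.station_id != reference]
    x = np.asarray(x, dtype=float)
    p0 = by_id[reference].position
    d0 = float(np.linalg.norm(x - p0))
    return np.array([(np.linalg.norm(x - by_id[i].position) - d0) / v for i in ids])


def _station_xy(stations: list[StationGeometry], t: TdoaSet) -> tuple[np.ndarray, np.ndarray]:
    by_id = {s.station_id: s for s in stations}
    ref_xy = by_id[t.reference_station].position
    xy = np.array([by_id[i].position for i in t.station_ids])
    return ref_xy, xy


def _pred_lags_vec(xs: np.ndarray, ref_xy: np.ndarray, xy: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Predicted lags for (n, 2) positions and (n,) wavespeeds -> (n, m)."""
    d0 = np.linalg.norm(xs - ref_xy, axis=-1)
    di = np.linalg.norm(xs[:, None, :] - xy[None, :, :], axis=-1)
    return (di - d0[:, None]) / np.asarray(v)[:, None]


def compute_residual(
    x: np.ndarray, v: float, t: TdoaSet, stations: list[StationGeometry]
) -> float:
    """Mean absolute TDOA mismatch in metres: v * mean_i |obs_i - pred_i|."""
    if v <= 0:
        raise ValueError("wavespeed must be > 0")
    pred = predict_tdoas(x, stations, t.reference_station, v, order=t.station_ids)
    return float(v * np.mean(np.abs(t.lags - pred)))


def joint_residual(
    x: np.ndarray,
    v_seis: float,
    v_acou: float,
    t_seis: TdoaSet,
    t_acou: TdoaSet,
    stations: list[StationGeometry],
) -> float:
    """Residual pooled over both modalities' station pairs."""
    ps = predict_tdoas(x, stations, t_seis.reference_station, v_seis, order=t_seis.station_ids)
    pa = predict_tdoas(x, stations, t_acou.reference_station, v_acou, order=t_acou.station_ids)
    errs = np.concatenate(
        [v_seis * np.abs(t_seis.lags - ps), v_acou * np.abs(t_acou.lags - pa)]
    )
    return float(errs.mean())


def best_estimate(candidates: list[LocationEstimate]) -> LocationEstimate:
    """Candidate with the smallest residual; ties go to the first occurrence."""
    if not candidates:
        raise ValueError("no candidate estimates")
    residuals = np.array([c.residual for c in candidates])
    return candidates[int(np.argmin(residuals))]


# ---------------------------------------------------------------------------
# models


class TdoaLocationModel:
    """Single-modality source localization model over one TDOA set.

    ``fit()`` runs the deterministic wavespeed-grid least-squares sweep;
    ``fit_probabilistic()`` samples the (x, y, v) posterior.
    """

    def __init__(
        self,
        tdoas: TdoaSet,
        stations: list[StationGeometry],
        config: SolverConfig | None = None,
    ):
        if len(tdoas.pairs) < 3:
            raise ValueError(
                f"need >= 3 station pairs (4 stations) for a unique planar fix, "
                f"got {len(tdoas.pairs)}"
            )
        self.tdoas = tdoas
        self.stations = stations
        self.config = config or SolverConfig()
        self._ref_xy, self._xy = _station_xy(stations, tdoas)
        self._obs = tdoas.lags

    # -- deterministic -----------------------------------------------------

    def _residual_vector(self, x: np.ndarray, v: float) -> np.ndarray:
        pred = _pred_lags_vec(x[None, :], self._ref_xy, self._xy, np.array([v]))[0]
        return self._obs - pred

    def _residual_jac(self, x: np.ndarray, v: float) -> np.ndarray:
        d0 = x - self._ref_xy
        n0 = max(np.linalg.norm(d0), 1e-12)
        di = x[None, :] - self._xy
        ni = np.maximum(np.linalg.norm(di, axis=1), 1e-12)
        return -(di / ni[:, None] - d0[None, :] / n0) / v

    def _multistart_points(self) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.config.prior_box(self.stations)
        gx = np.linspace(xmin, xmax, 3)
        gy = np.linspace(ymin, ymax, 3)
        return np.array([[x, y] for x in gx for y in gy])

    def fit(self) -> "DeterministicResults":
        grid = np.asarray(self.config.wavespeed_grid[self.tdoas.modality], dtype=float)
        if grid.size == 0:
            raise ValueError("empty wavespeed grid")
        starts = self._multistart_points()
        estimates: list[LocationEstimate] = []
        for v in grid:
            best_x, best_obj, ok = None, np.inf, False
            for x0 in starts:
                sol = optimize.least_squares(
                    self._residual_vector, x0, jac=self._residual_jac, args=(v,),
                    method="lm", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
                obj = float(2 * sol.cost)
                if obj < best_obj:
                    best_x, best_obj, ok = sol.x, obj, bool(sol.success)
            estimates.append(
                LocationEstimate(
                    x=best_x,
                    v=float(v),
                    residual=compute_residual(best_x, v, self.tdoas, self.stations),
                    method="det",
                    modality=self.tdoas.modality,
                    converged=ok,
                )
            )
        return DeterministicResults(self, estimates)

    # -- probabilistic -----------------------------------------------------

    def _log_prob(self, theta: np.ndarray) -> np.ndarray:
        """Vectorized log posterior for (n, 3) parameter rows."""
        theta = np.atleast_2d(theta)
        xs, vs = theta[:, :2], theta[:, 2]
        xmin, xmax, ymin, ymax = self.config.prior_box(self.stations)
        vlo, vhi = self.config.wavespeed_prior[self.tdoas.modality]
        ok = (
            (xs[:, 0] >= xmin) & (xs[:, 0] <= xmax)
            & (xs[:, 1] >= ymin) & (xs[:, 1] <= ymax)
            & (vs >= vlo) & (vs <= vhi)
        )
        lp = np.full(theta.shape[0], -np.inf)
        if ok.any():
            pred = _pred_lags_vec(xs[ok], self._ref_xy, self._xy, vs[ok])
            sig = self.config.tdoa_sigma
            lp[ok] = -0.5 * np.sum(((self._obs - pred) / sig) ** 2, axis=1)
        return lp

    def fit_probabilistic(self) -> "ProbabilisticResults":
        samples = _run_sampler(
            self._log_prob,
            self._prior_draw,
            ndim=3,
            config=self.config,
            param_names=("x", "y", "v"),
        )
        return ProbabilisticResults(self, samples, method="prob", modality=self.tdoas.modality)

    def _prior_draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.config.prior_box(self.stations)
        vlo, vhi = self.config.wavespeed_prior[self.tdoas.modality]
        return np.column_stack(
            [
                rng.uniform(xmin, xmax, n),
                rng.uniform(ymin, ymax, n),
                rng.uniform(vlo, vhi, n),
            ]
        )

    def _sample_residuals(self, samples: np.ndarray) -> np.ndarray:
        pred = _pred_lags_vec(samples[:, :2], self._ref_xy, self._xy, samples[:, 2])
        return samples[:, 2] * np.mean(np.abs(self._obs - pred), axis=1)


class JointTdoaLocationModel:
    """Bimodal localization: one position, independent per-medium wavespeeds.

    The likelihood is the product of the seismic and acoustic Gaussian TDOA
    terms, so both data sets constrain the shared position while each keeps
    its own wavespeed.
    """

    def __init__(
        self,
        tdoas_seismic: TdoaSet,
        tdoas_acoustic: TdoaSet,
        stations: list[StationGeometry],
        config: SolverConfig | None = None,
    ):
        if tdoas_seismic.event_id != tdoas_acoustic.event_id:
            raise ValueError("seismic and acoustic TDOA sets refer to different events")
        self.t_seis = tdoas_seismic
        self.t_acou = tdoas_acoustic
        self.stations = stations
        self.config = config or SolverConfig()
        self._ref_s, self._xy_s = _station_xy(stations, tdoas_seismic)
        self._ref_a, self._xy_a = _station_xy(stations, tdoas_acoustic)
        self._obs_s = tdoas_seismic.lags
        self._obs_a = tdoas_acoustic.lags

    def _log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        xs, vs, va = theta[:, :2], theta[:, 2], theta[:, 3]
        xmin, xmax, ymin, ymax = self.config.prior_box(self.stations)
        slo, shi = self.config.wavespeed_prior["seismic"]
        alo, ahi = self.config.wavespeed_prior["acoustic"]
        ok = (
            (xs[:, 0] >= xmin) & (xs[:, 0] <= xmax)
            & (xs[:, 1] >= ymin) & (xs[:, 1] <= ymax)
            & (vs >= slo) & (vs <= shi) & (va >= alo) & (va <= ahi)
        )
        lp = np.full(theta.shape[0], -np.inf)
        if ok.any():
            sig = self.config.tdoa_sigma
            ps = _pred_lags_vec(xs[ok], self._ref_s, self._xy_s, vs[ok])
            pa = _pred_lags_vec(xs[ok], self._ref_a, self._xy_a, va[ok])
            lp[ok] = -0.5 * (
                np.sum(((self._obs_s - ps) / sig) ** 2, axis=1)
                + np.sum(((self._obs_a - pa) / sig) ** 2, axis=1)
            )
        return lp

    def _prior_draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        xmin, xmax, ymin, ymax = self.config.prior_box(self.stations)
        slo, shi = self.config.wavespeed_prior["seismic"]
        alo, ahi = self.config.wavespeed_prior["acoustic"]
        return np.column_stack(
            [
                rng.uniform(xmin, xmax, n),
                rng.uniform(ymin, ymax, n),
                rng.uniform(slo, shi, n),
                rng.uniform(alo, ahi, n),
            ]
        )

    def fit(self) -> "ProbabilisticResults":
        samples = _run_sampler(
            self._log_prob,
            self._prior_draw,
            ndim=4,
            config=self.config,
            param_names=("x", "y", "v_seismic", "v_acoustic"),
        )
        return ProbabilisticResults(self, samples, method="joint", modality="both")

    def _sample_residuals(self, samples: np.ndarray) -> np.ndarray:
        ps = _pred_lags_vec(samples[:, :2], self._ref_s, self._xy_s, samples[:, 2])
        pa = _pred_lags_vec(samples[:, :2], self._ref_a, self._xy_a, samples[:, 3])
        errs_s = samples[:, 2, None] * np.abs(self._obs_s - ps)
        errs_a = samples[:, 3, None] * np.abs(self._obs_a - pa)
        return np.concatenate([errs_s, errs_a], axis=1).mean(axis=1)


def _initial_walkers(log_prob, prior_draw, ndim, nw, rng) -> np.ndarray:
    """Importance-weighted walker initialization.

    Draw a cloud from the prior and resample it by likelihood weight.  When
    the likelihood is nearly flat the weights are uniform and the walkers
    start as prior draws (already stationary); when it is sharp, the
    effective sample size collapses, so instead locate the mode from the
    best draw by local optimization and start the walkers in a Gaussian
    ball whose per-axis scale comes from the local curvature.
    """
    n_try = max(2048, 16 * nw)
    pts = prior_draw(rng, n_try)
    lps = log_prob(pts)
    finite = np.isfinite(lps)
    if not finite.any():
        raise ValueError(
            "prior box excludes all posterior mass: every drawn sample has "
            "log density -inf; widen position/wavespeed priors"
        )
    w = np.zeros(n_try)
    w[finite] = np.exp(lps[finite] - lps[finite].max())
    ess = w.sum() ** 2 / np.sum(w**2)
    if ess >= nw:
        idx = rng.choice(n_try, size=nw, replace=False, p=w / w.sum()) if ess >= n_try / 2 \
            else rng.choice(n_try, size=nw, replace=True, p=w / w.sum())
        p0 = pts[idx]
        # break ties from resampling with replacement
        span = pts[finite].std(axis=0)
        p0 = p0 + rng.normal(0.0, 1e-6, p0.shape) * span
        if np.all(np.isfinite(log_prob(p0))):
            return p0
    # moderately informative likelihood (log densities here are -0.5*chi^2,
    # so values above ~-25 mean the best draws already sit in the support
    # region): start from the top draws, which trace the high-density ridge
    if lps[finite].max() > -25.0:
        order = np.argsort(np.where(finite, lps, -np.inf))[::-1]
        return pts[order[:nw]].copy()
    # sharp likelihood: climb to the mode and size a ball from the curvature
    best = pts[int(np.nanargmax(np.where(finite, lps, -np.inf)))]
    res = optimize.minimize(
        lambda th: -float(log_prob(th[None, :])[0]), best, method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 6000, "maxfev": 6000},
    )
    mode = res.x if np.isfinite(res.fun) else best
    lp_mode = float(log_prob(mode[None, :])[0])
    scales = np.empty(ndim)
    for k in range(ndim):
        h = max(1e-6, 1e-6 * abs(mode[k]))
        for _ in range(60):  # grow h until the density drops measurably
            probe = np.vstack([mode, mode, mode])
            probe[1, k] += h
            probe[2, k] -= h
            lpp = log_prob(probe)
            drop = lp_mode - np.nanmax(lpp[1:][np.isfinite(lpp[1:])], initial=-np.inf)
            if not np.isfinite(lpp[1]) and not np.isfinite(lpp[2]):
                h /= 4.0
                break
            if drop >= 0.5:
                break
            h *= 2.0
        scales[k] = h
    p0 = mode[None, :] + rng.normal(0.0, 1.0, (nw, ndim)) * scales[None, :]
    lp0 = log_prob(p0)
    bad = ~np.isfinite(lp0)
    for _ in range(100):
        if not bad.any():
            break
        p0[bad] = mode[None, :] + rng.normal(0.0, 0.1, (bad.sum(), ndim)) * scales[None, :]
        lp0 = log_prob(p0)
        bad = ~np.isfinite(lp0)
    p0[bad] = mode
    return p0


def _run_sampler(log_prob, prior_draw, ndim, config: SolverConfig, param_names) -> PosteriorSamples:
    """Affine-invariant ensemble MCMC with a polished MAP sample appended."""
    rng = np.random.default_rng(config.rng_seed)
    nw = max(config.n_walkers, 2 * ndim + 2)
    p0 = _initial_walkers(log_prob, prior_draw, ndim, nw, rng)
    n_keep_steps = int(np.ceil(config.n_samples / nw))
    nsteps = config.n_burn + n_keep_steps
    sampler = emcee.EnsembleSampler(nw, ndim, log_prob, vectorize=True)
    state = emcee.State(p0, random_state=np.random.RandomState(config.rng_seed))
    sampler.run_mcmc(state, nsteps, progress=False)
    chain = sampler.get_chain(discard=config.n_burn, flat=True)
    lps = sampler.get_log_prob(discard=config.n_burn, flat=True)
    finite = np.isfinite(lps)
    chain, lps = chain[finite], lps[finite]
    # polish the best sample into the true MAP and append it
    i = int(np.argmax(lps))
    res = optimize.minimize(
        lambda th: -float(log_prob(th[None, :])[0]), chain[i], method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000},
    )
    if np.isfinite(res.fun) and -res.fun >= lps[i]:
        chain = np.vstack([chain, res.x])
        lps = np.append(lps, -res.fun)
    return PosteriorSamples(
        samples=chain, log_densities=lps, param_names=tuple(param_names), rng_seed=config.rng_seed
    )


# ---------------------------------------------------------------------------
# results


class DeterministicResults:
    """Grid-sweep output: one location estimate per wavespeed guess."""

    def __init__(self, model: TdoaLocationModel, estimates: list[LocationEstimate]):
        self.model = model
        self.estimates = estimates

    @property
    def best(self) -> LocationEstimate:
        return best_estimate(self.estimates)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "v": [e.v for e in self.estimates],
                "x": [e.x[0] for e in self.estimates],
                "y": [e.x[1] for e in self.estimates],
                "residual_m": [e.residual for e in self.estimates],
                "converged": [e.converged for e in self.estimates],
            }
        )

    def summary(self) -> str:
        b = self.best
        lines = [
            "Deterministic TDOA localization",
            f"  modality        : {self.model.tdoas.modality}",
            f"  station pairs   : {len(self.model.tdoas.pairs)}",
            f"  wavespeed grid  : {len(self.estimates)} guesses",
            f"  best wavespeed  : {b.v:.1f} m/s",
            f"  best position   : ({b.x[0]:.2f}, {b.x[1]:.2f}) m",
            f"  best residual   : {b.residual:.3f} m",
        ]
        return "\n".join(lines)


class ProbabilisticResults:
    """Posterior samples plus the residual-minimizing and MAP estimates."""

    def __init__(self, model, samples: PosteriorSamples, method: str, modality: str):
        self.model = model
        self.samples = samples
        self.method = method
        self.modality = modality
        self._residuals = model._sample_residuals(samples.samples)

    @property
    def sample_residuals(self) -> np.ndarray:
        return self._residuals

    def _estimate_from(self, i: int) -> LocationEstimate:
        s = self.samples.samples[i]
        v_acou = float(s[3]) if s.size == 4 else None
        return LocationEstimate(
            x=s[:2],
            v=float(s[2]),
            residual=float(self._residuals[i]),
            method=self.method,
            modality=self.modality,
            v_acoustic=v_acou,
        )

    @property
    def best(self) -> LocationEstimate:
        """Sample with the smallest residual (the reported location)."""
        return self._estimate_from(int(np.argmin(self._residuals)))

    @property
    def map_estimate(self) -> LocationEstimate:
        return self._estimate_from(self.samples.map_index)

    @property
    def posterior_mean(self) -> np.ndarray:
        return self.samples.samples.mean(axis=0)

    @property
    def posterior_sd(self) -> np.ndarray:
        return self.samples.samples.std(axis=0, ddof=1)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.samples.samples, columns=list(self.samples.param_names))
        df["log_density"] = self.samples.log_densities
        df["residual_m"] = self._residuals
        return df

    def summary(self) -> str:
        mean, sd = self.posterior_mean, self.posterior_sd
        b = self.best
        lines = [
            f"Probabilistic TDOA localization ({self.method}, {self.modality})",
            f"  posterior samples : {self.samples.samples.shape[0]}",
        ]
        for name, m, s in zip(self.samples.param_names, mean, sd):
            lines.append(f"  {name:<10}: {m:10.2f} +/- {s:.2f}")
        lines += [
            f"  best position     : ({b.x[0]:.2f}, {b.x[1]:.2f}) m",
            f"  best residual     : {b.residual:.3f} m",
        ]
        return "\n".join(lines)

    def plot(self, path=None, stations: list[StationGeometry] | None = None):
        """Scatter of posterior positions (and stations) without a basemap."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 6))
        pos = self.samples.positions
        ax.scatter(pos[:, 0], pos[:, 1], s=2, alpha=0.2, label="posterior samples")
        b = self.best
        ax.scatter(*b.x, marker="*", s=160, color="crimson", label="best estimate")
        sts = stations or getattr(self.model, "stations", None)
        if sts:
            xy = station_array(sts)
            ax.scatter(xy[:, 0], xy[:, 1], marker="^", s=80, color="k", label="stations")
            for s in sts:
                ax.annotate(s.station_id, (s.x, s.y), textcoords="offset points", xytext=(4, 4))
        ax.set_xlabel("easting (m)")
        ax.set_ylabel("northing (m)")
        ax.set_aspect("equal")
        ax.legend(loc="best", fontsize=8)
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig


# ---------------------------------------------------------------------------
# functional wrappers


def localize_deterministic(
    t: TdoaSet, stations: list[StationGeometry], cfg: SolverConfig | None = None
) -> list[LocationEstimate]:
    """Wavespeed-grid least-squares sweep; one estimate per grid wavespeed."""
    return TdoaLocationModel(t, stations, cfg).fit().estimates


def localize_probabilistic(
    t: TdoaSet, stations: list[StationGeometry], cfg: SolverConfig | None = None
) -> PosteriorSamples:
    """Posterior samples over (x, y, v) for one TDOA set."""
    return TdoaLocationModel(t, stations, cfg).fit_probabilistic().samples


def localize_joint(
    t_seis: TdoaSet,
    t_acou: TdoaSet,
    stations: list[StationGeometry],
    cfg: SolverConfig | None = None,
) -> PosteriorSamples:
    """Posterior samples over (x, y, v_seis, v_acou) for a bimodal event."""
    return JointTdoaLocationModel(t_seis, t_acou, stations, cfg).fit().samples
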