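"""Second-derivative preprocessing and PLSR with PRESS/F-test model selection.

The latent-variable count is chosen by comparing each simpler model's
cross-validated PRESS against the minimum-PRESS model with an F-ratio: the
smallest model not significantly worse than the best one is selected
(Haaland-Thomas convention, default alpha = 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import f as f_dist

from .errors import ConfigError, FoldSizeError, RankError, ShapeError
from .simulate import (
    LineComb,
    SceneConfig,
    alternating_trajectory,
    default_co2_comb,
    default_water_comb,
    simulate_series,
)
from .spectra import InterferentSpec, Region, Spectrum, region_indices
from .correction import correct_series

__all__ = [
    "DerivativeSpec",
    "PLSRModel",
    "LVSelection",
    "second_derivative",
    "fit_plsr",
    "press_by_group_cv",
    "select_lv_ftest",
    "LipidDemoConfig",
    "demo_lipid_pipeline",
]


@dataclass
class DerivativeSpec:
    """Savitzky-Golay second-derivative settings."""

    window: int = 11
    polyorder: int = 3

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ConfigError(f"window must be odd, got {self.window}")
        if self.polyorder < 2:
            raise ConfigError("polyorder must be >= 2 for a second derivative")
        if self.window <= self.polyorder:
            raise ConfigError(
                f"window ({self.window}) must exceed polyorder ({self.polyorder})"
            )


def second_derivative(s: Spectrum, spec: DerivativeSpec = DerivativeSpec()) -> Spectrum:
    """Savitzky-Golay second derivative with respect to sample index.

    Edge points come from one-sided polynomial fits; output length equals
    input length.
    """
    if len(s) < spec.window:
        raise ConfigError(
            f"window {spec.window} exceeds spectrum length {len(s)}"
        )
    d2 = savgol_filter(
        s.absorbance, spec.window, spec.polyorder, deriv=2, delta=1.0, mode="interp"
    )
    return s.with_absorbance(d2, derivative=2, sg_window=spec.window,
                             sg_polyorder=spec.polyorder)


@dataclass
class PLSRModel:
    """PLS1 factorization (NIPALS) on mean-centered data.

    ``n_lv`` is the requested component count; fewer may be extracted when
    the response is exhausted (``n_extracted``), in which case predictions
    for larger counts reuse the last extracted model.
    """

    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray  # (p, A)
    x_loadings: np.ndarray  # (p, A)
    y_loadings: np.ndarray  # (A,)
    scores: np.ndarray  # (n, A)
    n_extracted: int

    def coefficients(self, n_components: int | None = None) -> np.ndarray:
        """Regression vector of the first k components, in original X units."""
        k = self.n_extracted if n_components is None else min(
            n_components, self.n_extracted
        )
        if k < 1:
            raise RankError("model extracted no components")
        W = self.weights[:, :k]
        P = self.x_loadings[:, :k]
        q = self.y_loadings[:k]
        return W @ np.linalg.solve(P.T @ W, q)

    def predict(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        b = self.coefficients(n_components)
        return (X - self.x_mean) @ b + self.y_mean


def fit_plsr(X: np.ndarray, y: np.ndarray, n_lv: int) -> PLSRModel:
    """Fit a univariate-response PLS regression by NIPALS deflation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ShapeError(f"X {X.shape} does not match y of length {y.size}")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ShapeError("missing values are not supported")
    n, p = X.shape
    max_rank = min(n - 1, p)
    if not (1 <= n_lv <= max_rank):
        raise RankError(f"n_lv must be in [1, {max_rank}], got {n_lv}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean

    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    extracted = 0
    eps = np.finfo(float).eps
    scale = max(np.abs(Xc).max(), 1.0) * max(np.abs(yc).max(), 1.0)
    for a in range(n_lv):
        w = Xc.T @ yc
        wn = np.linalg.norm(w)
        if wn <= np.sqrt(eps) * scale:
            break  # response exhausted; remaining components undefined
        w /= wn
        t = Xc @ w
        tt = float(t @ t)
        if tt <= eps:
            break
        p_a = (Xc.T @ t) / tt
        q_a = float(yc @ t) / tt
        Xc = Xc - np.outer(t, p_a)
        yc = yc - q_a * t
        W[:, a], P[:, a], q[a], T[:, a] = w, p_a, q_a, t
        extracted += 1
    if extracted == 0:
        raise RankError("response is constant; no PLS component can be extracted")
    return PLSRModel(
        n_lv=n_lv,
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W[:, :extracted],
        x_loadings=P[:, :extracted],
        y_loadings=q[:extracted],
        scores=T[:, :extracted],
        n_extracted=extracted,
    )


def press_by_group_cv(
    X: np.ndarray, y: np.ndarray, groups: np.ndarray, max_lv: int
) -> np.ndarray:
    """Leave-one-group-out PRESS for 1..max_lv latent variables.

    PRESS(k) sums squared prediction errors over every held-out sample using
    a k-component model fit on the remaining groups.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    groups = np.asarray(groups)
    if groups.size != y.size:
        raise ShapeError("groups must have one entry per sample")
    uniq = np.unique(groups)
    if uniq.size < 2:
        raise FoldSizeError("need >= 2 groups for leave-one-group-out CV")
    press = np.zeros(max_lv)
    for g in uniq:
        held = groups == g
        train = ~held
        n_train = int(train.sum())
        if n_train < max_lv + 1:
            raise FoldSizeError(
                f"fold holding out group {g!r} leaves {n_train} training "
                f"samples; need >= {max_lv + 1}"
            )
        model = fit_plsr(X[train], y[train], max_lv)
        for k in range(1, max_lv + 1):
            pred = model.predict(X[held], n_components=k)
            press[k - 1] += float(np.sum((y[held] - pred) ** 2))
    return press


@dataclass
class LVSelection:
    press: np.ndarray
    k_min_press: int
    k_selected: int
    f_ratios: np.ndarray
    threshold: float
    probabilities: np.ndarray = field(default_factory=lambda: np.array([]))


def select_lv_ftest(
    press: np.ndarray, n_pred: int, alpha: float = 0.25
) -> LVSelection:
    """Pick the smallest LV count not significantly worse than the PRESS minimum.

    For each candidate k the ratio F(k) = PRESS(k) / min(PRESS) is referred
    to an F distribution with (n_pred, n_pred) degrees of freedom; the first
    k whose exceedance probability is above ``alpha`` is selected. The
    minimum itself has F = 1 (probability 0.5), so a selection always exists
    for alpha < 0.5.
    """
    press = np.asarray(press, dtype=float)
    if press.size == 0:
        raise ShapeError("PRESS vector is empty")
    if n_pred < 2:
        raise ShapeError(f"need >= 2 CV predictions, got {n_pred}")
    k_min = int(np.argmin(press)) + 1
    p_min = press[k_min - 1]
    if p_min == 0.0:
        # perfect fit: ratios are undefined; keep the minimum-PRESS model
        return LVSelection(press, k_min, k_min, np.full(press.size, np.nan),
                           alpha, np.full(press.size, np.nan))
    f_ratios = press / p_min
    probs = f_dist.sf(f_ratios, n_pred, n_pred)
    k_selected = k_min
    for k in range(1, k_min + 1):
        if probs[k - 1] > alpha:
            k_selected = k
            break
    return LVSelection(press, k_min, k_selected, f_ratios, alpha, probs)


# ---------------------------------------------------------------------------
# Synthetic binary-mixture demonstration
# ---------------------------------------------------------------------------

#: Gaussian band sets (center cm^-1, height AU per mM, fwhm cm^-1) for the two
#: lipid-like analytes; deliberately overlapping, with analyte A carrying a
#: carbonyl-like band inside the water-bend interference region.
_ANALYTE_A_BANDS = [(1060.0, 0.30, 40.0), (1145.0, 0.22, 35.0), (1740.0, 0.40, 30.0)]
_ANALYTE_B_BANDS = [(1085.0, 0.28, 45.0), (1145.0, 0.15, 35.0), (1720.0, 0.18, 28.0)]


@dataclass
class LipidDemoConfig:
    """Knobs for the synthetic binary-mixture PLSR demonstration."""

    n_runs: int = 40
    scans_per_run: int = 6
    conc_a_range: tuple[float, float] = (0.0, 1.7)  # mM
    conc_b_range: tuple[float, float] = (0.0, 0.83)  # mM
    axis: tuple[float, float, float] = (950.0, 2500.0, 4.0)
    interferent_amp: float = 0.08  # AU scale of vapor-comb fluctuation
    noise_sd: float = 0.002
    drift_slope: float = 0.001
    analysis_region: Region = field(default_factory=lambda: Region(960.0, 2450.0))
    test_fraction: float = 0.2
    max_lv: int = 12
    alpha: float = 0.25
    derivative: DerivativeSpec = field(default_factory=DerivativeSpec)


def _demo_interferents(cfg: LipidDemoConfig):
    """Fixed vapor bases shared by all runs: water bend + CO2 stretch combs."""
    water = (
        InterferentSpec("H2O-bend", Region(1205.0, 2072.0)),
        default_water_comb(seed=12345),
    )
    co2 = (
        InterferentSpec("CO2-asym-stretch", Region(2208.0, 2442.0)),
        default_co2_comb(seed=54321),
    )
    return [water, co2]


def _simulate_run(cfg: LipidDemoConfig, conc_a: float, conc_b: float,
                  interferents, seed: int):
    rng = np.random.default_rng(seed)
    scene_interferents = [
        (spec, comb,
         alternating_trajectory(rng, cfg.scans_per_run, cfg.interferent_amp))
        for spec, comb in interferents
    ]
    bands = [(c, h * conc_a, w) for c, h, w in _ANALYTE_A_BANDS]
    bands += [(c, h * conc_b, w) for c, h, w in _ANALYTE_B_BANDS]
    scene = SceneConfig(
        axis=cfg.axis,
        analyte_bands=bands,
        interferents=scene_interferents,
        noise_sd=cfg.noise_sd,
        drift=(cfg.drift_slope, 0.0),
        seed=seed,
    )
    return simulate_series(scene)


def demo_lipid_pipeline(cfg: LipidDemoConfig = LipidDemoConfig(), seed: int = 0) -> dict:
    """Run the full corrected-vs-uncorrected PLSR comparison on synthetic
    binary mixtures.

    Returns a report with, for each arm, the PRESS curve, the selected LV
    count and train/test R^2. Runs are split 80/20 into training and test by
    run (never by spectrum), and the uncorrected arm drops the same unpaired
    scan per run as the corrected arm so both train on identical counts.
    """
    rng = np.random.default_rng(seed)
    interferents = _demo_interferents(cfg)
    specs = [spec for spec, _ in interferents]

    conc_a = rng.uniform(*cfg.conc_a_range, size=cfg.n_runs)
    conc_b = rng.uniform(*cfg.conc_b_range, size=cfg.n_runs)

    X_corr, X_unc, y_all, run_ids = [], [], [], []
    for r in range(cfg.n_runs):
        run_seed = int(rng.integers(0, 2**31 - 1))
        series, _ = _simulate_run(cfg, conc_a[r], conc_b[r], interferents,
                                  run_seed)
        corrected, _ = correct_series(series, specs, pairing="next")
        for k in range(len(corrected)):
            X_corr.append(corrected[k].absorbance)
            X_unc.append(series[k].absorbance)
            y_all.append(conc_a[r])
            run_ids.append(r)

    axis = np.asarray(
        np.arange(cfg.axis[0], cfg.axis[1] + cfg.axis[2] / 2, cfg.axis[2])
    )
    i_lo, i_hi = region_indices(axis, cfg.analysis_region)

    def preprocess(rows: list[np.ndarray]) -> np.ndarray:
        out = np.empty((len(rows), i_hi - i_lo + 1))
        for i, row in enumerate(rows):
            d2 = savgol_filter(row, cfg.derivative.window, cfg.derivative.polyorder,
                               deriv=2, delta=1.0, mode="interp")
            out[i] = d2[i_lo : i_hi + 1]
        return out

    y = np.asarray(y_all)
    runs = np.asarray(run_ids)
    test_runs = rng.choice(cfg.n_runs, size=max(1, round(cfg.test_fraction * cfg.n_runs)),
                           replace=False)
    is_test = np.isin(runs, test_runs)

    report: dict = {"seed": seed, "n_spectra": int(y.size),
                    "n_train": int((~is_test).sum()), "n_test": int(is_test.sum())}
    for arm, rows in (("corrected", X_corr), ("uncorrected", X_unc)):
        Xd = preprocess(rows)
        Xtr, ytr, gtr = Xd[~is_test], y[~is_test], runs[~is_test]
        Xte, yte = Xd[is_test], y[is_test]
        press = press_by_group_cv(Xtr, ytr, gtr, cfg.max_lv)
        sel = select_lv_ftest(press, n_pred=ytr.size, alpha=cfg.alpha)
        model = fit_plsr(Xtr, ytr, sel.k_selected)
        pred_tr = model.predict(Xtr)
        pred_te = model.predict(Xte)
        report[arm] = {
            "press": press.tolist(),
            "k_min_press": sel.k_min_press,
            "k_selected": sel.k_selected,
            "train_r2": _r2(ytr, pred_tr),
            "test_r2": _r2(yte, pred_te),
        }
    return report


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot
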