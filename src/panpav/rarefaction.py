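"""Pan/core-genome rarefaction and saturation-model fitting.

Accessions are subsampled at every size n = 1..N over many random orderings;
within one ordering the size-n subset is the order's prefix, which makes each
iteration's pan curve non-decreasing and core curve non-increasing by
construction while each prefix is still a uniform random subset of size n.

Saturation is judged Tettelin-style: the mean pan curve is fitted with a
power law P(n) = A*n^gamma + C, the per-step gene discovery with
Delta(n) = k*n^(-alpha), and the mean core curve with exponential decay
K(n) = B*exp(-n/tau) + Omega. The pan-genome is called closed when alpha > 1
(new-gene discovery decays faster than 1/n, so the total converges); the core
genome is called open when the fitted core curve is still dropping by more
than half a gene per added accession at the full panel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import PavMatrix


@dataclass
class RarefactionCurves:
    sizes: np.ndarray
    pan_mean: np.ndarray
    pan_min: np.ndarray
    pan_max: np.ndarray
    core_mean: np.ndarray
    core_min: np.ndarray
    core_max: np.ndarray
    n_iterations: int
    seed: int | None = None
    # per-iteration curves (iterations x sizes), kept for points-mode fitting
    pan_all: np.ndarray | None = field(default=None, repr=False)
    core_all: np.ndarray | None = field(default=None, repr=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "size": self.sizes,
                "pan_mean": self.pan_mean,
                "pan_min": self.pan_min,
                "pan_max": self.pan_max,
                "core_mean": self.core_mean,
                "core_min": self.core_min,
                "core_max": self.core_max,
            }
        )


def pan_core_curves(
    matrix: PavMatrix,
    n_iterations: int = 100,
    seed: int | None = None,
    exhaustive: bool = False,
) -> RarefactionCurves:
    """Monte-Carlo pan/core gene counts over random accession subsets.

    pan(n) = genes present in >= 1 of the n sampled accessions; core(n) =
    genes present in all n. At n = 1 the two coincide; at n = N pan equals the
    number of genes seen anywhere and core the number at frequency 1.
    With ``exhaustive`` every subset of every size is enumerated instead
    (feasible only for small panels); n_iterations and seed are ignored.
    """
    if exhaustive:
        return _exhaustive_curves(matrix)
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    pres = matrix.presence.astype(bool)
    g, n = pres.shape
    pan = np.empty((n_iterations, n), dtype=np.int64)
    core = np.empty((n_iterations, n), dtype=np.int64)
    for it in range(n_iterations):
        order = rng.permutation(n)
        cols = pres[:, order]
        pan[it] = np.logical_or.accumulate(cols, axis=1).sum(axis=0)
        core[it] = np.logical_and.accumulate(cols, axis=1).sum(axis=0)
    return RarefactionCurves(
        sizes=np.arange(1, n + 1),
        pan_mean=pan.mean(axis=0),
        pan_min=pan.min(axis=0),
        pan_max=pan.max(axis=0),
        core_mean=core.mean(axis=0),
        core_min=core.min(axis=0),
        core_max=core.max(axis=0),
        n_iterations=n_iterations,
        seed=seed,
        pan_all=pan,
        core_all=core,
    )


def _exhaustive_curves(matrix: PavMatrix) -> RarefactionCurves:
    from itertools import combinations

    pres = matrix.presence.astype(bool)
    n = pres.shape[1]
    pan_stats, core_stats = [], []
    for size in range(1, n + 1):
        pans, cores = [], []
        for subset in combinations(range(n), size):
            cols = pres[:, subset]
            pans.append(int(cols.any(axis=1).sum()))
            cores.append(int(cols.all(axis=1).sum()))
        pan_stats.append((np.mean(pans), np.min(pans), np.max(pans)))
        core_stats.append((np.mean(cores), np.min(cores), np.max(cores)))
    pan_stats = np.array(pan_stats)
    core_stats = np.array(core_stats)
    return RarefactionCurves(
        sizes=np.arange(1, n + 1),
        pan_mean=pan_stats[:, 0], pan_min=pan_stats[:, 1].astype(int), pan_max=pan_stats[:, 2].astype(int),
        core_mean=core_stats[:, 0], core_min=core_stats[:, 1].astype(int), core_max=core_stats[:, 2].astype(int),
        n_iterations=0, seed=None,
    )


@dataclass
class SaturationFit:
    """Fitted saturation models and the openness verdicts."""

    pan_params: dict | None          # A, gamma, C
    newgene_params: dict | None      # k, alpha
    core_params: dict | None         # B, tau, Omega
    pan_rss: float | None
    core_rss: float | None
    pan_verdict: str | None          # closed | open
    core_verdict: str | None
    diagnostics: list[str] = field(default_factory=list)


def _power(n, a, gamma, c):
    return a * np.power(n, gamma) + c


def _decay(n, k, alpha):
    return k * np.power(n, -alpha)


def _expdrop(n, b, tau, omega):
    return b * np.exp(-n / tau) + omega


def fit_saturation(curves: RarefactionCurves, use_points: bool = False) -> SaturationFit:
    """Least-squares saturation fits on the mean curves (or all iteration points).

    Non-convergence of a component fit is reported in ``diagnostics`` and that
    verdict is withheld rather than guessed.
    """
    sizes = curves.sizes.astype(float)
    if len(sizes) < 4:
        raise ValueError("need at least 4 distinct subsample sizes to fit")
    if use_points and curves.pan_all is not None:
        x_pan = np.tile(sizes, curves.pan_all.shape[0])
        y_pan = curves.pan_all.ravel().astype(float)
        x_core = x_pan
        y_core = curves.core_all.ravel().astype(float)
    else:
        x_pan, y_pan = sizes, curves.pan_mean.astype(float)
        x_core, y_core = sizes, curves.core_mean.astype(float)

    diags: list[str] = []
    pan_params = core_params = new_params = None
    pan_rss = core_rss = None
    pan_verdict = core_verdict = None

    span = float(y_pan.max() - y_pan.min())
    try:
        p, _ = curve_fit(
            _power, x_pan, y_pan,
            p0=[max(span, 1.0), 0.3, float(y_pan.min())],
            bounds=([0.0, 0.0, -np.inf], [np.inf, 1.0, np.inf]),
            maxfev=20000,
        )
        pan_params = {"A": p[0], "gamma": p[1], "C": p[2]}
        pan_rss = float(np.sum((_power(x_pan, *p) - y_pan) ** 2))
    except RuntimeError as err:
        diags.append(f"pan power-law fit failed: {err}")

    # new-gene discovery: successive differences of the mean pan curve
    delta = np.diff(curves.pan_mean.astype(float))
    ns = sizes[1:]
    pos = delta > 0
    if pos.sum() == 0:
        # flat pan curve: no discovery at any size; trivially saturated
        new_params = {"k": 0.0, "alpha": np.inf}
        pan_verdict = "closed"
    elif pos.sum() < 2:
        diags.append("too few positive discovery steps to fit decay model")
    else:
        try:
            p, _ = curve_fit(
                _decay, ns[pos], delta[pos],
                p0=[float(delta[pos][0]), 1.0],
                bounds=([0.0, 1e-9], [np.inf, np.inf]),
                maxfev=20000,
            )
            new_params = {"k": p[0], "alpha": p[1]}
            pan_verdict = "closed" if p[1] > 1.0 else "open"
        except RuntimeError as err:
            diags.append(f"new-gene decay fit failed: {err}")

    try:
        b0 = float(y_core.max() - y_core.min())
        p, _ = curve_fit(
            _expdrop, x_core, y_core,
            p0=[max(b0, 1.0), max(len(sizes) / 10.0, 1.0), float(y_core.min())],
            bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        core_params = {"B": p[0], "tau": p[1], "Omega": p[2]}
        core_rss = float(np.sum((_expdrop(x_core, *p) - y_core) ** 2))
        n_full = sizes[-1]
        still_dropping = abs(_expdrop(n_full, *p) - _expdrop(n_full - 1, *p)) > 0.5
        core_verdict = "open" if still_dropping else "closed"
    except RuntimeError as err:
        diags.append(f"core exponential fit failed: {err}")

    return SaturationFit(
        pan_params=pan_params,
        newgene_params=new_params,
        core_params=core_params,
        pan_rss=pan_rss,
        core_rss=core_rss,
        pan_verdict=pan_verdict,
        core_verdict=core_verdict,
        diagnostics=diags,
    )
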