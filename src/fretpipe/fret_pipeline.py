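"""Per-frame FRET efficiencies, summed histograms, and Gaussian decomposition.

The efficiency of each accepted molecule is computed frame-by-frame as

    E = I_A / (I_A + gamma * I_D)

over the region before acceptor photobleaching, with the per-molecule gamma
from QC and the per-trace baseline subtracted from both channels.  Molecules
contribute equally to the summed histogram regardless of how long they
survived: each trace's frames are binned with weight 1/(number of frames in
the trace), into 40 equal bins spanning -0.25 to 1.25 (the margins absorb
noise excursions outside the physical range).  The summed histogram is then
decomposed into a sum of Gaussian components by nonlinear least squares, and
each component is reported with its mean, width, and fractional area
(analytic area share), the quantities used to read conformational-state
populations off the distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize

from .trace_qc import QCResult
from .trace_sim import IntensityTrace

__all__ = [
    "FretTrace",
    "FretHistogram",
    "GaussianMixtureFit",
    "FitError",
    "EmptyInputError",
    "compute_fret",
    "build_histogram",
    "fit_mixture",
    "HIST_RANGE",
    "N_BINS",
]

HIST_RANGE = (-0.25, 1.25)
N_BINS = 40
MAX_DROP_FRACTION = 0.2


class FitError(RuntimeError):
    """Mixture fit failed to converge; carries the fit report."""


class EmptyInputError(ValueError):
    pass


@dataclass
class FretTrace:
    """Efficiency series for one molecule over its pre-acceptor-bleach frames."""

    molecule_id: str
    E: np.ndarray
    gamma: float
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.E = np.asarray(self.E, dtype=float)
        if self.E.ndim != 1 or len(self.E) < 1:
            raise ValueError("E must be a 1-D series of length >= 1")


@dataclass
class FretHistogram:
    """Summed, per-trace-normalized efficiency distribution."""

    bin_edges: np.ndarray
    weights: np.ndarray
    n_molecules: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "weight": self.weights,
            }
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class GaussianComponent:
    mean: float
    sd: float
    fractional_area: float
    amplitude: float
    sd_at_bound: bool = False


@dataclass
class GaussianMixtureFit:
    components: list[GaussianComponent]
    residual_sse: float
    n_components: int
    success: bool = True

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def fractional_areas(self) -> np.ndarray:
        return np.array([c.fractional_area for c in self.components])

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "residual_sse": self.residual_sse,
            "components": [
                {
                    "mean": c.mean,
                    "sd": c.sd,
                    "fractional_area": c.fractional_area,
                    "amplitude": c.amplitude,
                    "sd_at_bound": c.sd_at_bound,
                }
                for c in self.components
            ],
        }


def compute_fret(trace: IntensityTrace, qc: QCResult) -> FretTrace:
    """Gamma-corrected per-frame efficiency before acceptor photobleaching.

    The QC baseline (post-donor-bleach level of both channels) is subtracted
    from both channels first.  Frames where the corrected total I_A + gamma*I_D
    is non-positive are dropped and counted; if more than 20% of frames drop,
    the whole molecule is discarded.
    """
    if not qc.accepted or qc.gamma is None or qc.acceptor_bleach is None:
        raise ValueError("compute_fret requires an accepted QC result")
    k = qc.acceptor_bleach.step_frame
    donor = trace.donor[:k] - qc.baseline
    acceptor = trace.acceptor[:k] - qc.baseline
    denom = acceptor + qc.gamma * donor
    keep = denom > 0
    n_dropped = int((~keep).sum())
    if len(denom) == 0 or n_dropped / len(denom) > MAX_DROP_FRACTION:
        raise ValueError(
            f"{trace.molecule_id}: {n_dropped}/{len(denom)} frames with non-positive total"
        )
    e = acceptor[keep] / denom[keep]
    return FretTrace(trace.molecule_id, e, gamma=qc.gamma, n_dropped=n_dropped)


def build_histogram(
    fret_traces: Sequence[FretTrace],
    min_points: int = 20,
) -> FretHistogram:
    """Summed histogram with per-trace normalization.

    Only traces strictly longer than ``min_points`` frames (2 s at 100 ms)
    contribute.  Each retained trace's frames are binned with weight
    1/(trace length), so every molecule carries total weight 1; efficiencies
    outside the histogram range are discarded.
    """
    edges = np.linspace(*HIST_RANGE, N_BINS + 1)
    retained = [ft for ft in fret_traces if len(ft.E) > min_points]
    if not retained:
        raise EmptyInputError("no traces longer than min_points")
    weights = np.zeros(N_BINS)
    for ft in retained:
        h, _ = np.histogram(ft.E, bins=edges)
        weights += h / len(ft.E)
    return FretHistogram(bin_edges=edges, weights=weights, n_molecules=len(retained))


def sample_from_mixture(
    means: Sequence[float],
    sds: Sequence[float] | float,
    weights: Sequence[float],
    n: int,
    seed: int = 0,
) -> np.ndarray:
    """Draw efficiencies from a Gaussian mixture (weights are normalized, so
    percent areas that round to a sum slightly off 100 are accepted)."""
    means = np.asarray(means, float)
    weights = np.asarray(weights, float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("mixture weights must be nonnegative with positive sum")
    sds = np.broadcast_to(np.asarray(sds, float), means.shape)
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(means), p=weights / weights.sum(), size=n)
    return rng.normal(means[comp], sds[comp])


def _gaussian_sum(x: np.ndarray, params: Parameters, n: int) -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(n):
        amp = params[f"amp{i}"].value
        mu = params[f"mu{i}"].value
        sd = params[f"sd{i}"].value
        y = y + amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def fit_mixture(
    hist: FretHistogram,
    n_components: int,
    init: Sequence[float] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    shared_sd: bool = False,
) -> GaussianMixtureFit:
    """Fit a sum of Gaussians to the histogram by nonlinear least squares.

    Unweighted least squares of bin heights at bin centers.  Means are bounded
    to the histogram range; widths are bounded below at half the bin width
    (collapsed components are reported flagged at the bound).  Unless ``init``
    is given, means start at weighted quantiles of the histogram and
    ``n_restarts`` jittered restarts (deterministic sub-seeds) guard against
    local minima; the best-SSE solution wins.  Components come back sorted by
    mean, with fractional areas ``amp_i sd_i / sum_j amp_j sd_j`` (the
    analytic Gaussian area share, the convention used for state populations).

    ``shared_sd=True`` ties all component widths to a single fitted value.
    Overlapping components with free widths are weakly identified on a
    finite-sample histogram (a small shoulder can trade its mean against its
    width almost freely); when the physical widths are expected to be equal
    (shot-noise-dominated broadening), the shared-width constraint removes
    that degeneracy.
    """
    if not 1 <= n_components <= 4:
        raise ValueError("n_components must be between 1 and 4")
    x = hist.bin_centers
    y = hist.weights
    bin_w = x[1] - x[0]
    sd_min = bin_w / 2
    lo, hi = HIST_RANGE

    if init is not None:
        if len(init) != n_components:
            raise ValueError("init must provide one mean per component")
        base_means = np.asarray(init, dtype=float)
    else:
        # weighted quantiles of the histogram: lands one start per mode for
        # well-separated components
        cw = np.cumsum(y)
        if cw[-1] <= 0:
            raise FitError("histogram has no weight")
        q = (np.arange(n_components) + 0.5) / n_components
        base_means = np.interp(q * cw[-1], cw, x)

    rng = np.random.default_rng(seed)
    amp0 = max(y.max(), 1e-6)
    best = None
    for r in range(n_restarts):
        means = base_means if r == 0 else base_means + rng.normal(0, 0.05, n_components)
        params = Parameters()
        for i in range(n_components):
            params.add(f"amp{i}", value=amp0 / n_components, min=0)
            params.add(f"mu{i}", value=float(np.clip(means[i], lo, hi)), min=lo, max=hi)
            if shared_sd and i > 0:
                params.add(f"sd{i}", expr="sd0")
            else:
                params.add(f"sd{i}", value=0.08, min=sd_min, max=(hi - lo) / 2)

        def residual(p):
            return _gaussian_sum(x, p, n_components) - y

        try:
            out = minimize(residual, params, method="leastsq")
        except Exception:
            continue
        sse = float(np.sum(out.residual**2))
        if best is None or sse < best[0]:
            best = (sse, out)

    if best is None:
        raise FitError("all mixture-fit restarts failed")
    sse, out = best

    comps = []
    for i in range(n_components):
        amp = out.params[f"amp{i}"].value
        mu = out.params[f"mu{i}"].value
        sd = out.params[f"sd{i}"].value
        comps.append((mu, sd, amp))
    comps.sort(key=lambda c: c[0])
    areas = np.array([amp * sd for mu, sd, amp in comps])
    total_area = areas.sum()
    if total_area <= 0:
        raise FitError("degenerate fit: zero total area")
    components = [
        GaussianComponent(
            mean=float(mu),
            sd=float(sd),
            fractional_area=float(a / total_area),
            amplitude=float(amp),
            sd_at_bound=bool(np.isclose(sd, sd_min)),
        )
        for (mu, sd, amp), a in zip(comps, areas)
    ]
    return GaussianMixtureFit(
        components=components,
        residual_sse=sse,
        n_components=n_components,
        success=bool(out.success),
    )


def read_traces(path: str | Path, frame_interval_s: float = 0.1) -> list[IntensityTrace]:
    """Read an ensemble TSV (molecule_id, frame, donor, acceptor)."""
    df = pd.read_csv(path, sep="\t")
    traces = []
    for mid, g in df.groupby("molecule_id", sort=True):
        g = g.sort_values("frame")
        traces.append(
            IntensityTrace(
                molecule_id=str(mid),
                donor=g["donor"].to_numpy(float),
                acceptor=g["acceptor"].to_numpy(float),
                frame_interval_s=frame_interval_s,
            )
        )
    return traces
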