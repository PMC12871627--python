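"""Synthetic single-molecule FRET trace generation.

Emulates a two-color TIRF acquisition: each molecule carries a donor and an
acceptor dye, intensities are integrated over fixed frames (default 100 ms for
80 s, i.e. 800 frames), and each dye photobleaches in a single irreversible
step after an exponentially distributed waiting time.  Before acceptor bleach
the acceptor channel reads the transferred fraction ``E`` of the total
emission budget and the donor the remainder (scaled by the per-molecule
detection-imbalance factor gamma); after acceptor bleach all emission returns
to the donor; after donor bleach both channels fall to background.

Every trace carries its generating ground truth so downstream stages
(photobleach detection, gamma estimation, efficiency recovery) can be
benchmarked without experimental data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimParams",
    "SimTruth",
    "IntensityTrace",
    "simulate_trace",
    "simulate_ensemble",
    "write_traces",
    "write_truth",
]


class ParameterError(ValueError):
    """Raised when simulation parameters violate their invariants."""


@dataclass(frozen=True)
class SimTruth:
    """Generating ground truth for one simulated molecule."""

    E_true: float
    gamma_true: float
    acceptor_bleach_frame: int | None
    donor_bleach_frame: int | None


@dataclass
class IntensityTrace:
    """Paired donor/acceptor intensity time series for one molecule.

    Intensities are in photons/frame (arbitrary camera units in practice);
    ``frame_interval_s`` converts frame indices to seconds.
    """

    molecule_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval_s: float = 0.1
    truth: SimTruth | None = None

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.acceptor.ndim != 1:
            raise ParameterError("donor and acceptor must be 1-D series")
        if len(self.donor) != len(self.acceptor) or len(self.donor) < 1:
            raise ParameterError("donor and acceptor series must have equal length >= 1")

    def __len__(self) -> int:
        return len(self.donor)


@dataclass(frozen=True)
class SimParams:
    """Acquisition and photophysics parameters for the trace simulator.

    states : list of (E_true, weight)
        Static FRET states of the sample; per-molecule E_true is drawn from
        this discrete distribution (weights sum to 1).
    total_intensity : float
        Mean combined photon budget per frame before bleaching.
    noise_sd : float
        Additive Gaussian read noise per channel, photons/frame.
    gamma_mean, gamma_sd : float
        Per-molecule detection-imbalance factor gamma ~ N(mean, sd),
        truncated to positive values.
    donor_bleach_rate, acceptor_bleach_rate : float
        Single-step photobleaching hazard, 1/s.
    markov_rate_s : float
        Optional two-state switching rate (1/s) between the first two states;
        0 (default) keeps each molecule in a single static state, matching
        the static-mixture reading of summed histograms.
    """

    n_molecules: int = 1
    n_frames: int = 800
    frame_interval_s: float = 0.1
    states: Sequence[tuple[float, float]] = ((0.5, 1.0),)
    total_intensity: float = 100.0
    noise_sd: float = 5.0
    gamma_mean: float = 1.0
    gamma_sd: float = 0.1
    donor_bleach_rate: float = 0.015
    acceptor_bleach_rate: float = 0.05
    background: float = 0.0
    seed: int = 0
    poisson_noise: bool = False
    markov_rate_s: float = 0.0

    def __post_init__(self) -> None:
        if self.n_molecules < 1:
            raise ParameterError("n_molecules must be >= 1")
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be positive")
        if not self.states:
            raise ParameterError("at least one FRET state is required")
        weights = np.array([w for _, w in self.states], dtype=float)
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0, atol=1e-9):
            raise ParameterError("state weights must be nonnegative and sum to 1")
        for e, _ in self.states:
            if not 0.0 <= e <= 1.0:
                raise ParameterError(f"state efficiency {e} outside [0, 1]")
        for name in (
            "total_intensity",
            "noise_sd",
            "gamma_mean",
            "gamma_sd",
            "donor_bleach_rate",
            "acceptor_bleach_rate",
            "background",
            "markov_rate_s",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


def _molecule_rng(master_seed: int, molecule_seed: int) -> np.random.Generator:
    # Derived per-molecule stream: ensembles are order-independent.
    return np.random.default_rng(np.random.SeedSequence((master_seed, molecule_seed)))


def _draw_bleach_frame(rng: np.random.Generator, rate_per_s: float, params: SimParams) -> int | None:
    """Exponential waiting time -> first dark frame index, or None if the dye
    survives the record."""
    if rate_per_s == 0:
        return None
    t = rng.exponential(1.0 / rate_per_s)
    frame = int(np.floor(t / params.frame_interval_s))
    return frame if frame < params.n_frames else None


def simulate_trace(params: SimParams, molecule_seed: int) -> IntensityTrace:
    """Simulate one molecule's donor/acceptor trace.

    The molecule's state, gamma, and bleach times are all drawn from a stream
    seeded by ``(params.seed, molecule_seed)``, so a given molecule is
    reproducible regardless of ensemble order.
    """
    rng = _molecule_rng(params.seed, molecule_seed)

    e_values = np.array([e for e, _ in params.states])
    weights = np.array([w for _, w in params.states])
    state_idx = int(rng.choice(len(e_values), p=weights / weights.sum()))
    e_true = float(e_values[state_idx])

    gamma = -1.0
    while gamma <= 0:
        gamma = rng.normal(params.gamma_mean, params.gamma_sd)

    a_bleach = _draw_bleach_frame(rng, params.acceptor_bleach_rate, params)
    d_bleach = _draw_bleach_frame(rng, params.donor_bleach_rate, params)

    n = params.n_frames
    e_series = np.full(n, e_true)
    if params.markov_rate_s > 0 and len(e_values) >= 2:
        # Stress-test mode: symmetric two-state Markov switching between the
        # first two listed states.
        p_switch = 1.0 - np.exp(-params.markov_rate_s * params.frame_interval_s)
        cur = state_idx if state_idx < 2 else 0
        for i in range(n):
            e_series[i] = e_values[cur]
            if rng.random() < p_switch:
                cur = 1 - cur

    total = params.total_intensity
    acceptor = total * e_series
    donor = total * (1.0 - e_series) / gamma

    if a_bleach is not None:
        acceptor[a_bleach:] = 0.0
        donor[a_bleach:] = total / gamma  # all emission reverts to the donor
    if d_bleach is not None:
        donor[d_bleach:] = 0.0
        if a_bleach is None or d_bleach < a_bleach:
            acceptor[d_bleach:] = 0.0  # no donor excitation, no transfer

    if params.poisson_noise:
        donor = rng.poisson(np.maximum(donor, 0)).astype(float)
        acceptor = rng.poisson(np.maximum(acceptor, 0)).astype(float)

    donor = donor + params.background
    acceptor = acceptor + params.background
    if params.noise_sd > 0:
        donor = donor + rng.normal(0.0, params.noise_sd, n)
        acceptor = acceptor + rng.normal(0.0, params.noise_sd, n)

    # Effective bleach order seen by the trace: if the donor died first the
    # acceptor never had a separate bleach step.
    truth_a = a_bleach
    if a_bleach is not None and d_bleach is not None and d_bleach <= a_bleach:
        truth_a = None
    truth = SimTruth(
        E_true=e_true,
        gamma_true=float(gamma),
        acceptor_bleach_frame=truth_a,
        donor_bleach_frame=d_bleach,
    )
    return IntensityTrace(
        molecule_id=f"mol{molecule_seed:05d}",
        donor=donor,
        acceptor=acceptor,
        frame_interval_s=params.frame_interval_s,
        truth=truth,
    )


def simulate_ensemble(params: SimParams) -> list[IntensityTrace]:
    """Simulate ``params.n_molecules`` independent traces."""
    return [simulate_trace(params, i) for i in range(params.n_molecules)]


def write_traces(traces: Sequence[IntensityTrace], path: str | Path) -> None:
    """Write an ensemble as plain TSV: molecule_id, frame, donor, acceptor."""
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": np.arange(len(tr)),
                    "donor": tr.donor,
                    "acceptor": tr.acceptor,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_truth(traces: Sequence[IntensityTrace], path: str | Path) -> None:
    """Write the sidecar ground-truth table for a simulated ensemble."""
    rows = []
    for tr in traces:
        t = tr.truth
        if t is None:
            continue
        rows.append(
            {
                "molecule_id": tr.molecule_id,
                "E_true": t.E_true,
                "gamma_true": t.gamma_true,
                "acceptor_bleach_frame": -1 if t.acceptor_bleach_frame is None else t.acceptor_bleach_frame,
                "donor_bleach_frame": -1 if t.donor_bleach_frame is None else t.donor_bleach_frame,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
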