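"""Synthetic inputs: noisy strain-force curves and fixture chip geometries.

Real DEP-stretching datasets are per-level means over tens of cells with
standard errors; this module emulates that statistical structure from
the network model itself.  Each synthetic "cell" is one network
realization whose strain is read at every force level; an additive
zero-mean Gaussian observation error (microscopy strain readout noise)
is layered on top, and levels are aggregated to mean, SE = sd/sqrt(n)
and n.  Everything is deterministic under a fixed seed, so generated
CSV fixtures are bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .actin_network import (
    NetworkParams,
    RelaxConfig,
    StrainForceCurve,
    strain_matrix,
)
from .electrokinetics import Drive
from .field_solver import ChipModel, ElectrodeSegment, default_chip


@dataclass(frozen=True)
class NoiseModel:
    """Observation-noise model for synthetic strain readouts.

    ``strain_sd`` is the per-cell, per-level standard deviation of the
    strain measurement error; ``n_cells`` mirrors the study design of
    examining more than 50 cells per group.
    """

    strain_sd: float = 0.03
    n_cells: int = 50

    def __post_init__(self) -> None:
        if self.strain_sd < 0:
            raise ValueError("strain_sd must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def generate_strain_force_data(
    true_params: NetworkParams,
    forces: np.ndarray,
    noise: NoiseModel,
    seed: int,
    config: RelaxConfig | None = None,
    label: str = "synthetic",
) -> StrainForceCurve:
    """Simulate a mean +/- SE strain-force curve with observation noise.

    One network realization per cell (seeds spawned from ``seed`` exactly
    as in :func:`cytostretch.actin_network.simulate_stretch_curve`, so
    with ``strain_sd=0, n_cells=1`` the output equals the plain simulated
    curve); Gaussian noise of sd ``strain_sd`` is added to every cell's
    strain at every level before aggregation, hence the reported SE is
    consistent with the per-cell spread and n by construction.
    """
    forces = np.asarray(forces, dtype=float)
    mat = strain_matrix(true_params, forces, noise.n_cells, seed, config=config)
    if noise.strain_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
        mat = mat + rng.normal(0.0, noise.strain_sd, size=mat.shape)
    se = (
        mat.std(axis=1, ddof=1) / math.sqrt(noise.n_cells)
        if noise.n_cells > 1
        else np.zeros(len(mat))
    )
    return StrainForceCurve(
        force=forces,
        strain_mean=mat.mean(axis=1),
        strain_se=se,
        n=np.full(len(mat), noise.n_cells),
        label=label,
    )


def make_fixture_chip(kind: str, voltage_amplitude: float = 2.0) -> ChipModel:
    """Fixture chip geometries for tests and examples.

    ``parallel_plate``: driven bottom wall, grounded top wall, gap equal
    to the domain height — admits the analytic uniform field E = U/d.
    ``tip_to_tip``: the default coplanar-electrode chip with the 20 um
    gap on the bottom wall.
    """
    if kind == "parallel_plate":
        w = h = 50e-6
        return ChipModel(
            domain_width=w,
            domain_height=h,
            electrodes=(
                ElectrodeSegment("bottom", 0.0, w, voltage_amplitude),
                ElectrodeSegment("top", 0.0, w, 0.0),
            ),
            gap=h,
            grid_spacing=0.5e-6,
        )
    if kind == "tip_to_tip":
        return default_chip(voltage_amplitude=voltage_amplitude)
    raise ValueError(f"unknown fixture chip kind {kind!r}")


def paper_table1_protocol() -> list[Drive]:
    """The six-voltage stretching protocol: 1.5-4 V amplitude at 1 MHz.

    Amplitudes correspond to the 3-8 V peak-to-peak stretching range
    (amplitude = V_pp / 2).
    """
    return [Drive(voltage_amplitude=u, frequency=1e6) for u in
            (1.5, 2.0, 2.5, 3.0, 3.5, 4.0)]
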