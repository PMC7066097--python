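"""Analytic three-layer spherical-head forward model for EEG and MEG.

The head is modelled as three concentric spheres (brain, skull, scalp) with
piecewise-constant isotropic conductivity -- the classical Ary geometry of
87 / 92 / 100 mm radii and 0.33 / 0.0042 / 0.33 S/m.  Scalp potentials of a
current dipole are obtained from the multilayer-sphere Legendre series with
point electrodes and an average reference; the radial magnetic field outside
the conductor follows the Sarvas result, by which volume currents in a
spherically symmetric conductor contribute nothing to the radial component,
so the radial lead field equals the free-space field of the primary dipole.

Conventions
-----------
* Positions are held in millimetres at the interface and converted to SI
  units internally.  EEG lead-field entries are in Ohm/m (volts per unit
  dipole moment), MEG entries in 1/m^2 (radial primary field with the
  mu_0 / 4 pi prefactor factored out; any global scale cancels in the
  Frobenius fusion and max-normalization applied downstream).
* Each source position carries three dipole components along the Cartesian
  axes.  The current-density vector ``x`` of the observation model
  ``y = L x + n`` is position-major: entry ``3 i + c`` is component
  ``c`` (0=x, 1=y, 2=z) of position ``i``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateDataError,
    DimensionError,
    GeometryError,
    ParameterError,
)

MM = 1e-3  # millimetres to metres

__all__ = [
    "HeadModel",
    "SensorArray",
    "SourceSpace",
    "LeadField",
    "DipoleSource",
    "MeasurementSet",
    "upper_hemisphere_sensors",
    "magnetometers_from_electrodes",
    "build_source_space",
    "eeg_leadfield",
    "meg_radial_leadfield",
    "simulate_data",
    "combine_emeg",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeadModel:
    """Concentric-spheres conductor.

    Parameters
    ----------
    layer_radii : tuple of float
        Outer radius of each layer in mm, innermost first, strictly
        increasing.  Default is the Ary model (87, 92, 100).
    conductivities : tuple of float
        Conductivity of each layer in S/m.  Default (0.33, 0.0042, 0.33)
        for grey matter, skull and scalp.
    series_truncation : int
        Maximum Legendre degree of the potential expansion.
    series_tol : float
        Relative tail tolerance; the series is cut as soon as three
        consecutive degrees each change the accumulated columns by less
        than this fraction, or at `series_truncation`, whichever first.
    """

    layer_radii: tuple[float, ...] = (87.0, 92.0, 100.0)
    conductivities: tuple[float, ...] = (0.33, 0.0042, 0.33)
    series_truncation: int = 100
    series_tol: float = 1e-8

    def __post_init__(self) -> None:
        r = np.asarray(self.layer_radii, dtype=float)
        c = np.asarray(self.conductivities, dtype=float)
        if r.size != c.size:
            raise ParameterError("layer_radii and conductivities must pair up")
        if not np.all(np.diff(r) > 0) or r[0] <= 0:
            raise ParameterError("layer radii must be positive and strictly increasing")
        if not np.all(c > 0):
            raise ParameterError("conductivities must be positive")
        if self.series_truncation < 1:
            raise ParameterError("series_truncation must be >= 1")

    @property
    def inner_radius(self) -> float:
        return float(self.layer_radii[0])

    @property
    def outer_radius(self) -> float:
        return float(self.layer_radii[-1])


@dataclass(frozen=True)
class SensorArray:
    """A set of point sensors: scalp electrodes or radial magnetometers."""

    kind: str  # "electrode" | "radial_magnetometer"
    positions: np.ndarray  # (m, 3) in mm

    def __post_init__(self) -> None:
        if self.kind not in ("electrode", "radial_magnetometer"):
            raise ParameterError(f"unknown sensor kind {self.kind!r}")
        object.__setattr__(
            self, "positions", np.atleast_2d(np.asarray(self.positions, dtype=float))
        )
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ParameterError("sensor positions must be (m, 3)")

    @property
    def count(self) -> int:
        return self.positions.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.positions, columns=["x_mm", "y_mm", "z_mm"])
        df.insert(0, "id", np.arange(self.count))
        df["kind"] = self.kind
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SensorArray":
        df = pd.read_csv(path)
        kind = str(df["kind"].iloc[0]) if "kind" in df else "electrode"
        return cls(kind=kind, positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy())


@dataclass(frozen=True)
class SourceSpace:
    """Candidate source positions inside the innermost sphere.

    Each of the K positions carries three Cartesian dipole components, so
    the unknown current-density vector has length 3 K with the
    position-major layout documented in the module docstring.
    """

    positions: np.ndarray  # (K, 3) in mm
    r_min: float = 0.0
    r_max: float = np.inf

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "positions", np.atleast_2d(np.asarray(self.positions, dtype=float))
        )
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ParameterError("source positions must be (K, 3)")

    @property
    def n_positions(self) -> int:
        return self.positions.shape[0]

    @property
    def n_components(self) -> int:
        return 3 * self.positions.shape[0]

    def radii(self) -> np.ndarray:
        return np.linalg.norm(self.positions, axis=1)

    def nearest(self, point_mm) -> int:
        """Index of the source position nearest to ``point_mm``."""
        d = np.linalg.norm(self.positions - np.asarray(point_mm, float), axis=1)
        return int(np.argmin(d))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.positions, columns=["x_mm", "y_mm", "z_mm"])
        df.insert(0, "id", np.arange(self.n_positions))
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SourceSpace":
        df = pd.read_csv(path)
        return cls(positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy())


@dataclass
class LeadField:
    """Sensitivity matrix of the observation model ``y = L x + n``.

    ``matrix`` has one row per sensor and three columns per source
    position.  ``space`` retains the source geometry so that downstream
    code can match dipoles to columns and evaluate region-of-interest
    metrics without re-threading the positions separately.
    """

    matrix: np.ndarray  # (m, 3K)
    modality: str  # "EEG" | "MEG" | "EMEG"
    units: str
    space: SourceSpace | None = None
    sensors: SensorArray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise DimensionError("lead field must be a 2-D matrix")
        if self.matrix.shape[1] % 3:
            raise DimensionError("lead field must have 3 columns per source position")
        if self.space is not None and self.matrix.shape[1] != self.space.n_components:
            raise DimensionError("lead field columns do not match the source space")
        if not np.all(np.isfinite(self.matrix)):
            raise ParameterError("lead field contains non-finite entries")

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("matrix", data=self.matrix)
            f.attrs["modality"] = self.modality
            f.attrs["units"] = self.units
            if self.space is not None:
                f.create_dataset("source_positions_mm", data=self.space.positions)
            if self.sensors is not None:
                f.create_dataset("sensor_positions_mm", data=self.sensors.positions)
                f.attrs["sensor_kind"] = self.sensors.kind

    @classmethod
    def from_hdf5(cls, path) -> "LeadField":
        import h5py

        with h5py.File(path, "r") as f:
            space = None
            sensors = None
            if "source_positions_mm" in f:
                space = SourceSpace(positions=f["source_positions_mm"][()])
            if "sensor_positions_mm" in f:
                sensors = SensorArray(
                    kind=str(f.attrs.get("sensor_kind", "electrode")),
                    positions=f["sensor_positions_mm"][()],
                )
            return cls(
                matrix=f["matrix"][()],
                modality=str(f.attrs["modality"]),
                units=str(f.attrs["units"]),
                space=space,
                sensors=sensors,
            )

    def to_text(self, matrix_path, sidecar_path) -> None:
        np.savetxt(matrix_path, self.matrix)
        meta = {
            "modality": self.modality,
            "units": self.units,
            "layout": "position-major: column 3*i+c is Cartesian component c of position i",
            "shape": list(self.matrix.shape),
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=1)


@dataclass(frozen=True)
class DipoleSource:
    """A current dipole: position (mm), unit direction, scalar amplitude."""

    position: np.ndarray
    moment_direction: np.ndarray
    amplitude: float

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=float).reshape(3)
        d = np.asarray(self.moment_direction, dtype=float).reshape(3)
        n = np.linalg.norm(d)
        if n == 0:
            raise ParameterError("moment_direction must be non-zero")
        object.__setattr__(self, "position", p)
        object.__setattr__(self, "moment_direction", d / n)
        object.__setattr__(self, "amplitude", float(self.amplitude))

    @property
    def moment(self) -> np.ndarray:
        return self.amplitude * self.moment_direction


@dataclass
class MeasurementSet:
    """Simulated sensor data, max-normalized so that ``max |y| = 1``.

    ``sigma`` is the white-noise standard deviation on the normalized
    scale; ``clean_y`` is the noiseless signal on the same scale, and
    ``normalization_factor`` restores the raw amplitudes.
    """

    y: np.ndarray
    sigma: float
    clean_y: np.ndarray
    normalization_factor: float

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.clean_y = np.asarray(self.clean_y, dtype=float).ravel()
        if self.y.shape != self.clean_y.shape:
            raise DimensionError("y and clean_y must have the same length")


# ---------------------------------------------------------------------------
# geometry builders
# ---------------------------------------------------------------------------

def upper_hemisphere_sensors(count: int = 102, radius_mm: float = 100.0) -> SensorArray:
    """Quasi-uniform electrode layout on the upper hemisphere (z >= 0).

    A deterministic Fibonacci spiral; the experimental literature places
    the sensors over the upper hemisphere but publishes no coordinates, so
    any quasi-uniform layout is acceptable.
    """
    if count < 1:
        raise ParameterError("count must be >= 1")
    i = np.arange(count)
    z = (i + 0.5) / count  # uniform in [0, 1): cos(polar angle)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    s = np.sqrt(1.0 - z**2)
    pos = radius_mm * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    return SensorArray(kind="electrode", positions=pos)


def magnetometers_from_electrodes(
    electrodes: SensorArray, scale: float = 1.2
) -> SensorArray:
    """Radial magnetometers at the electrode locations scaled outward."""
    return SensorArray(
        kind="radial_magnetometer", positions=scale * electrodes.positions
    )


def build_source_space(
    K: int, r_min: float, r_max: float, seed=None, head: HeadModel | None = None
) -> SourceSpace:
    """Sample K source positions uniformly in the shell r_min <= r <= r_max.

    The radius is drawn by inverse-CDF sampling (density proportional to
    r^2), the direction uniformly on the sphere, which together give the
    uniform distribution in the shell volume.
    """
    if K < 1:
        raise ParameterError("K must be >= 1")
    if not (0 <= r_min < r_max):
        raise ParameterError("need 0 <= r_min < r_max")
    if head is not None and r_max >= head.inner_radius:
        raise ParameterError("r_max must lie strictly inside the innermost sphere")
    rng = np.random.default_rng(seed)
    u = rng.random(K)
    r = np.cbrt(r_min**3 + u * (r_max**3 - r_min**3))
    v = rng.standard_normal((K, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return SourceSpace(positions=r[:, None] * v, r_min=r_min, r_max=r_max)


# ---------------------------------------------------------------------------
# EEG: multilayer-sphere Legendre series
# ---------------------------------------------------------------------------

def _transfer_factors(head: HeadModel, n_max: int) -> np.ndarray:
    """Degree-wise surface transfer factors T_n of the layered sphere.

    For each Legendre degree n the potential in layer k is
    ``a_k r^n + b_k r^-(n+1)`` plus, in the source layer, the known
    infinite-medium singular term.  Enforcing continuity of the potential
    and of the radial current at the interfaces and zero radial current at
    the scalp yields a small linear system per degree; T_n is the ratio of
    the resulting surface coefficient to the infinite-medium surface
    coefficient.  For a homogeneous sphere T_n = (2n+1)/n exactly.

    Radii are scaled by the outer radius so the matrices stay
    well-conditioned up to high degree.
    """
    rho = np.asarray(head.layer_radii, float) / head.outer_radius
    sig = np.asarray(head.conductivities, float)
    n_layers = rho.size
    n_arr = np.arange(1, n_max + 1, dtype=float)
    if n_layers == 1:
        return (2 * n_arr + 1) / n_arr

    n_unk = 2 * n_layers - 1  # a_1, then (a_k, b_k) for k = 2..n_layers
    A = np.zeros((n_max, n_unk, n_unk))
    rhs = np.zeros((n_max, n_unk))
    for idx, n in enumerate(n_arr):
        row = 0
        for k in range(n_layers - 1):  # interface between layer k and k+1
            r = rho[k]
            rp = r**n  # r^n
            rm = r ** -(n + 1)  # r^-(n+1)
            dp = n * r ** (n - 1)
            dm = -(n + 1) * r ** -(n + 2)
            ca = 0 if k == 0 else 2 * k - 1  # column of a_k
            cb = 2 * k  # column of b_k (absent for k = 0)
            can, cbn = 2 * k + 1, 2 * k + 2  # columns of a_{k+1}, b_{k+1}
            # potential continuity
            A[idx, row, ca] += rp
            if k > 0:
                A[idx, row, cb] += rm
            A[idx, row, can] -= rp
            A[idx, row, cbn] -= rm
            rhs[idx, row] = 0.0 if k > 0 else -rm
            row += 1
            # radial current continuity
            A[idx, row, ca] += sig[k] * dp
            if k > 0:
                A[idx, row, cb] += sig[k] * dm
            A[idx, row, can] -= sig[k + 1] * dp
            A[idx, row, cbn] -= sig[k + 1] * dm
            rhs[idx, row] = 0.0 if k > 0 else -sig[k] * dm
            row += 1
        # insulating exterior at rho = 1
        A[idx, row, n_unk - 2] = n
        A[idx, row, n_unk - 1] = -(n + 1)
    sol = np.linalg.solve(A, rhs[..., None])[..., 0]
    return sol[:, n_unk - 2] + sol[:, n_unk - 1]  # surface value a_N + b_N


def eeg_leadfield(
    space: SourceSpace, sensors: SensorArray, head: HeadModel | None = None
) -> LeadField:
    """Average-referenced scalp-potential lead field of the layered sphere.

    Column ``3 i + c`` holds the potentials of a unit dipole along
    Cartesian axis ``c`` at position ``i``, in Ohm/m.  The degree-n term
    of the series is the infinite-medium dipole harmonic scaled by the
    layered-sphere transfer factor; writing the gradient with respect to
    the source position through the Legendre recurrences keeps every term
    finite down to a dipole at the origin.
    """
    head = head or HeadModel()
    if sensors.kind != "electrode":
        raise GeometryError("EEG requires an electrode array")
    R = head.outer_radius
    er = np.linalg.norm(sensors.positions, axis=1)
    if np.any(np.abs(er - R) > 1e-6 * R):
        raise GeometryError("electrodes must lie on the outer sphere surface")
    b = space.radii()
    if np.any(b >= head.inner_radius):
        raise GeometryError("sources must lie strictly inside the innermost sphere")

    T = _transfer_factors(head, head.series_truncation)
    t = b / R  # scaled source radii, < 1
    # cos of the angle between each electrode and each source position
    with np.errstate(invalid="ignore", divide="ignore"):
        u = (sensors.positions @ space.positions.T) / (R * b[None, :])
    u = np.where(b[None, :] > 0, u, 0.0)
    np.clip(u, -1.0, 1.0, out=u)

    m, K = sensors.count, space.n_positions
    # S1 multiplies the source position, S2 the electrode position
    S1 = np.zeros((m, K))
    S2 = np.zeros((m, K))
    P_prev = np.ones_like(u)  # P_0
    P_cur = u.copy()  # P_1
    dP_prev = np.zeros_like(u)  # P_0'
    dP_cur = np.ones_like(u)  # P_1'
    t_pow = np.ones_like(t)  # t^(n-1)
    quiet = 0
    for n in range(1, head.series_truncation + 1):
        if n > 1:
            P_next = ((2 * n - 1) * u * P_cur - (n - 1) * P_prev) / n
            dP_next = dP_prev + (2 * n - 1) * P_cur
            P_prev, P_cur = P_cur, P_next
            dP_prev, dP_cur = dP_cur, dP_next
            t_pow = t_pow * t
        # t_pow = t^(n-1); dP_prev = P'_{n-1}, dP_cur = P'_n
        d1 = T[n - 1] * (t_pow / np.where(t > 0, t, 1.0)) * (-dP_prev) if n > 1 else 0.0
        d2 = T[n - 1] * t_pow * dP_cur
        if n > 1:
            S1 += d1
        S2 += d2
        tail = np.max(np.abs(d2)) / max(np.max(np.abs(S2)), 1e-300)
        quiet = quiet + 1 if tail < head.series_tol else 0
        if quiet >= 3:
            break

    scale = 1.0 / (4 * np.pi * head.conductivities[0] * (R * MM) ** 3)
    pos_m = space.positions * MM
    sens_m = sensors.positions * MM
    L = np.empty((m, 3 * K))
    for c in range(3):
        L[:, c::3] = scale * (S1 * pos_m[None, :, c] + S2 * sens_m[:, c][:, None])
    L -= L.mean(axis=0, keepdims=True)  # average reference
    return LeadField(matrix=L, modality="EEG", units="Ohm/m", space=space, sensors=sensors)


# ---------------------------------------------------------------------------
# MEG: radial field via the Sarvas result
# ---------------------------------------------------------------------------

def meg_radial_leadfield(
    space: SourceSpace, sensors: SensorArray, head: HeadModel | None = None
) -> LeadField:
    """Radial-magnetometer lead field in a spherically symmetric conductor.

    Volume currents contribute no radial field component, so each entry is
    the radial component of the free-space primary-dipole field,
    ``r_hat . (q x d) / |d|^3`` with ``d`` the sensor-source offset (the
    constant mu_0 / 4 pi is factored out, giving entries in 1/m^2).
    Radial dipoles are therefore exactly silent.
    """
    if sensors.kind != "radial_magnetometer":
        raise GeometryError("MEG requires a radial magnetometer array")
    sens = sensors.positions * MM
    srcs = space.positions * MM
    rs = np.linalg.norm(sens, axis=1)
    conductor = (head.outer_radius if head is not None else np.max(space.radii())) * MM
    if np.any(rs <= conductor):
        raise GeometryError("magnetometers must lie strictly outside the conductor")
    rhat = sens / rs[:, None]
    d = sens[:, None, :] - srcs[None, :, :]  # (m, K, 3)
    d3 = np.linalg.norm(d, axis=2) ** 3
    m, K = sens.shape[0], srcs.shape[0]
    L = np.empty((m, 3 * K))
    # r_hat . (e_c x d) = (r_hat x e_c) . (-d)? use e_c x d explicitly
    for c in range(3):
        e = np.zeros(3)
        e[c] = 1.0
        cross = np.cross(np.broadcast_to(e, d.shape), d)
        L[:, c::3] = np.einsum("mj,mkj->mk", rhat, cross) / d3
    return LeadField(
        matrix=L, modality="MEG", units="1/m^2", space=space, sensors=sensors
    )


# ---------------------------------------------------------------------------
# data simulation and modality fusion
# ---------------------------------------------------------------------------

def source_vector(space: SourceSpace, dipoles: list[DipoleSource]) -> np.ndarray:
    """Embed dipoles in the source space as a length-3K coefficient vector.

    Each dipole is assigned to the nearest candidate position; a warning is
    issued if that position is more than 5 mm away.
    """
    x = np.zeros(space.n_components)
    for dip in dipoles:
        i = space.nearest(dip.position)
        dist = np.linalg.norm(space.positions[i] - dip.position)
        if dist > 5.0:
            warnings.warn(
                f"dipole at {dip.position} is {dist:.1f} mm from the nearest "
                "source position",
                stacklevel=2,
            )
        x[3 * i : 3 * i + 3] += dip.moment
    return x


def simulate_data(
    lead: LeadField,
    dipoles: list[DipoleSource],
    noise_pct: float,
    seed=None,
) -> MeasurementSet:
    """Simulate noisy sensor data for a set of dipoles.

    Zero-mean Gaussian white noise with standard deviation ``noise_pct``
    percent of the maximal clean signal amplitude is added, after which the
    dataset is max-normalized to one; ``sigma`` is reported on the
    normalized scale.
    """
    if lead.space is None:
        raise ParameterError("lead field must carry its source space")
    if noise_pct < 0:
        raise ParameterError("noise_pct must be >= 0")
    active = [d for d in dipoles if d.amplitude != 0.0]
    if not active and noise_pct == 0:
        raise DegenerateDataError("no active dipoles and no noise: data would be zero")
    x = source_vector(lead.space, active)
    clean = lead.matrix @ x
    sigma_raw = (noise_pct / 100.0) * np.max(np.abs(clean)) if clean.size else 0.0
    rng = np.random.default_rng(seed)
    y_raw = clean + sigma_raw * rng.standard_normal(clean.shape)
    f = np.max(np.abs(y_raw))
    if f == 0:
        raise DegenerateDataError("simulated data is identically zero")
    return MeasurementSet(
        y=y_raw / f, sigma=sigma_raw / f, clean_y=clean / f, normalization_factor=f
    )


def simulate_emeg_data(
    L_eeg: LeadField,
    L_meg: LeadField,
    dipoles: list[DipoleSource],
    noise_pct: float,
    seed=None,
) -> MeasurementSet:
    """Simulate a combined E/MEG dataset with per-modality noise.

    Each modality receives white noise at ``noise_pct`` percent of its own
    maximal clean amplitude (each instrument has its own noise floor), the
    MEG block is scaled by the Frobenius factor ``c`` together with its
    lead field, and the stacked dataset is max-normalized jointly.  The
    recorded ``sigma`` is the EEG-block noise std on the normalized scale,
    which coincides with ``noise_pct`` percent of the global maximum
    whenever the EEG block attains it.
    """
    if L_eeg.space is None or L_meg.space is None:
        raise ParameterError("lead fields must carry their source space")
    active = [d for d in dipoles if d.amplitude != 0.0]
    if not active and noise_pct == 0:
        raise DegenerateDataError("no active dipoles and no noise: data would be zero")
    x = source_vector(L_eeg.space, active)
    clean_e = L_eeg.matrix @ x
    clean_m = L_meg.matrix @ x
    c = np.linalg.norm(L_eeg.matrix) / np.linalg.norm(L_meg.matrix)
    rng = np.random.default_rng(seed)
    sig_e = (noise_pct / 100.0) * np.max(np.abs(clean_e))
    sig_m = (noise_pct / 100.0) * np.max(np.abs(clean_m))
    y_e = clean_e + sig_e * rng.standard_normal(clean_e.shape)
    y_m = clean_m + sig_m * rng.standard_normal(clean_m.shape)
    y_raw = np.concatenate([y_e, c * y_m])
    clean = np.concatenate([clean_e, c * clean_m])
    f = np.max(np.abs(y_raw))
    if f == 0:
        raise DegenerateDataError("simulated data is identically zero")
    return MeasurementSet(
        y=y_raw / f, sigma=sig_e / f, clean_y=clean / f, normalization_factor=f
    )


def combine_emeg(
    L_eeg: LeadField,
    L_meg: LeadField,
    y_eeg: MeasurementSet | None = None,
    y_meg: MeasurementSet | None = None,
):
    """Fuse EEG and MEG into one system by Frobenius-norm matching.

    The MEG lead-field block and its data are both multiplied by
    ``c = ||L_eeg||_F / ||L_meg||_F`` so the two blocks carry equal
    Frobenius norm, then the systems are row-stacked.  With data omitted
    only the fused lead field is returned (the form used by the experiment
    pipeline, which simulates one consistent dataset directly from the
    fused matrix).
    """
    if L_eeg.matrix.shape[1] != L_meg.matrix.shape[1]:
        raise DimensionError("EEG and MEG lead fields must share the source space")
    if (
        L_eeg.space is not None
        and L_meg.space is not None
        and not np.array_equal(L_eeg.space.positions, L_meg.space.positions)
    ):
        raise DimensionError("EEG and MEG source spaces differ")
    c = np.linalg.norm(L_eeg.matrix) / np.linalg.norm(L_meg.matrix)
    fused = LeadField(
        matrix=np.vstack([L_eeg.matrix, c * L_meg.matrix]),
        modality="EMEG",
        units="Ohm/m (EEG block), scaled 1/m^2 (MEG block)",
        space=L_eeg.space,
        sensors=L_eeg.sensors,
    )
    if y_eeg is None and y_meg is None:
        return fused
    if y_eeg is None or y_meg is None:
        raise ParameterError("provide both data vectors or neither")
    data = MeasurementSet(
        y=np.concatenate([y_eeg.y, c * y_meg.y]),
        sigma=y_eeg.sigma,
        clean_y=np.concatenate([y_eeg.clean_y, c * y_meg.clean_y]),
        normalization_factor=y_eeg.normalization_factor,
    )
    return fused, data
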