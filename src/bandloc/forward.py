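"""Cortical patch model and lead field.

The lead field is the linear map from patch source amplitudes (one scalar
per patch: dipoles are fixed perpendicular to the cortical surface) to
sensor potentials.  Two routes produce it:

* an analytic four-shell concentric-sphere head model (brain / CSF / skull /
  scalp), solved per spherical-harmonic order as a small boundary-value
  problem and summed as a truncated Legendre series; or
* a file loader for lead fields computed externally with a realistic
  (FDM/FEM/BEM) head model.

Coordinates are a right-handed head frame in mm with the origin at the
sphere center; potentials are in µV per unit dipole moment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from .errors import ConvergenceError, FormatError, GeometryError

__all__ = [
    "SensorArray",
    "CorticalPatchModel",
    "ConductivityProfile",
    "LeadField",
    "build_spherical_lead_field",
    "load_lead_field",
    "save_lead_field",
    "apply_common_average",
    "DEFAULT_RADII_MM",
]

#: Default shell radii in mm: brain, CSF, skull, scalp (typical adult head).
DEFAULT_RADII_MM = (80.0, 81.0, 86.0, 92.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SensorArray:
    """Electrode labels, 3D positions (mm) and a symmetric neighbor relation."""

    labels: list[str]
    positions: np.ndarray  # (n_sensors, 3) mm
    adjacency: np.ndarray | None = None  # (n, n) bool, symmetric, irreflexive

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise FormatError("sensor positions must be (n, 3)")
        if len(self.labels) != self.positions.shape[0]:
            raise FormatError("label count does not match position count")
        if len(set(self.labels)) != len(self.labels):
            raise FormatError("sensor labels must be unique")
        if not np.all(np.isfinite(self.positions)):
            raise FormatError("sensor positions must be finite")
        if self.adjacency is not None:
            a = np.asarray(self.adjacency, dtype=bool)
            if a.shape != (self.n_sensors, self.n_sensors):
                raise FormatError("adjacency shape mismatch")
            if np.any(np.diag(a)):
                raise FormatError("adjacency must be irreflexive")
            if not np.array_equal(a, a.T):
                raise FormatError("adjacency must be symmetric")
            self.adjacency = a

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    @classmethod
    def from_file(cls, path, adjacency_neighbors: int | None = None) -> "SensorArray":
        """Read a whitespace-delimited ``label x y z`` file (mm, one sensor per line)."""
        labels: list[str] = []
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                if len(parts) != 4:
                    raise FormatError(f"expected 'label x y z', got: {line!r}")
                labels.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        arr = cls(labels, np.array(rows, dtype=float))
        if adjacency_neighbors:
            arr.adjacency = make_adjacency(arr.positions, adjacency_neighbors)
        return arr

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for lab, (x, y, z) in zip(self.labels, self.positions):
                fh.write(f"{lab} {x:.6f} {y:.6f} {z:.6f}\n")


def make_adjacency(positions: np.ndarray, n_neighbors: int = 6) -> np.ndarray:
    """Symmetric k-nearest-neighbor adjacency between sensors.

    Two sensors are neighbors if either is among the other's ``n_neighbors``
    nearest; the relation is symmetrized by union, which keeps it usable on
    irregular layouts.
    """
    from scipy.spatial import cKDTree

    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    k = min(n_neighbors + 1, n)
    _, idx = cKDTree(positions).query(positions, k=k)
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in idx[i, 1:]:
            adj[i, j] = adj[j, i] = True
    np.fill_diagonal(adj, False)
    return adj


@dataclass
class CorticalPatchModel:
    """Dipole-patch source space: centers (mm), unit orientations, hemispheres."""

    centers: np.ndarray       # (n_patches, 3) mm
    orientations: np.ndarray  # (n_patches, 3), unit norm
    hemisphere: np.ndarray    # (n_patches,) of 'L' / 'R'

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.hemisphere = np.asarray(self.hemisphere, dtype="U1")
        if self.centers.shape != self.orientations.shape or self.centers.shape[1] != 3:
            raise FormatError("centers and orientations must both be (n, 3)")
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise FormatError("patch orientations must have unit norm (±1e-9)")
        if not set(np.unique(self.hemisphere)) <= {"L", "R"}:
            raise FormatError("hemisphere labels must be 'L' or 'R'")

    @property
    def n_patches(self) -> int:
        return self.centers.shape[0]

    def hemisphere_indices(self, hemi: str) -> np.ndarray:
        return np.flatnonzero(self.hemisphere == hemi)

    @classmethod
    def from_file(cls, path) -> "CorticalPatchModel":
        """Read delimited ``patch_id x y z ox oy oz hemisphere`` rows."""
        centers, orients, hemis = [], [], []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                if len(parts) != 8:
                    raise FormatError(f"expected 8 columns, got {len(parts)}")
                centers.append([float(v) for v in parts[1:4]])
                orients.append([float(v) for v in parts[4:7]])
                hemis.append(parts[7])
        return cls(np.array(centers), np.array(orients), np.array(hemis))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for i in range(self.n_patches):
                c, o = self.centers[i], self.orientations[i]
                fh.write(
                    f"{i} {c[0]:.6f} {c[1]:.6f} {c[2]:.6f} "
                    f"{o[0]:.9f} {o[1]:.9f} {o[2]:.9f} {self.hemisphere[i]}\n"
                )


@dataclass
class ConductivityProfile:
    """Per-shell conductivities in S/m.

    ``eyeball`` and ``white_matter`` are literature values carried along for
    completeness; a concentric-sphere model has no compartment for them and
    they are never used by :func:`build_spherical_lead_field`.
    """

    scalp: float = 0.44
    skull: float = 0.018
    csf: float = 1.79
    brain: float = 0.25   # gray matter
    eyeball: float = 1.5       # unused by the spherical model
    white_matter: float = 0.35  # unused by the spherical model

    def __post_init__(self) -> None:
        for name in ("scalp", "skull", "csf", "brain"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"conductivity {name} must be > 0")

    def shells_inner_to_outer(self) -> np.ndarray:
        return np.array([self.brain, self.csf, self.skull, self.scalp])


@dataclass
class LeadField:
    """Sensors × patches gain matrix (µV per unit dipole moment)."""

    matrix: np.ndarray
    reference: str = "raw"  # 'raw' | 'common-average'
    sensors: SensorArray | None = field(default=None, repr=False)
    patches: CorticalPatchModel | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.all(np.isfinite(self.matrix)):
            raise FormatError("lead field entries must be finite")
        if self.reference not in ("raw", "common-average"):
            raise FormatError(f"unknown reference tag {self.reference!r}")

    @property
    def n_sensors(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_patches(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# analytic multi-shell spherical model
# ---------------------------------------------------------------------------

def _shell_transfer(n_orders: int, radii: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """Per-order scalp transfer coefficients for a concentric-shell conductor.

    For each spherical-harmonic order n the radial profile in shell k is
    A_k r^n + B_k r^-(n+1); the primary (dipole-in-infinite-medium) field
    contributes a unit r^-(n+1) term in the innermost shell.  Continuity of
    potential and of radial current at each interface plus the insulating
    outer boundary give a small linear system per order.  Radii are scaled
    by the scalp radius so the system stays well conditioned at high n.

    Returns ``t[n-1]`` = potential coefficient at the scalp surface for
    orders n = 1..n_orders.
    """
    n_shells = len(radii)
    r = np.asarray(radii, dtype=float) / radii[-1]  # scaled, r[-1] == 1
    t = np.empty(n_orders)
    if n_shells == 1:
        # insulated homogeneous sphere: A_1 = (n+1)/n, scalp term 1 + A_1
        n_arr = np.arange(1, n_orders + 1, dtype=float)
        return (2 * n_arr + 1) / n_arr
    n_unknowns = 2 * n_shells - 1  # A_1, then (A_k, B_k) for k >= 2
    for n in range(1, n_orders + 1):
        M = np.zeros((n_unknowns, n_unknowns))
        rhs = np.zeros(n_unknowns)

        def a_col(k: int) -> int:  # column of A_k
            return 0 if k == 1 else 2 * k - 3

        def b_col(k: int) -> int:  # column of B_k (k >= 2)
            return 2 * k - 2

        row = 0
        for k in range(1, n_shells):  # interface between shell k and k+1 at r[k-1]
            ri = r[k - 1]
            pw, iw = ri**n, ri ** -(n + 1)
            dpw, diw = n * ri ** (n - 1), -(n + 1) * ri ** -(n + 2)
            # potential continuity
            M[row, a_col(k)] = pw
            if k >= 2:
                M[row, b_col(k)] = iw
            M[row, a_col(k + 1)] = -pw
            M[row, b_col(k + 1)] = -iw
            rhs[row] = -iw if k == 1 else 0.0  # primary field lives in shell 1
            row += 1
            # radial current continuity
            sk, sk1 = sigmas[k - 1], sigmas[k]
            M[row, a_col(k)] = sk * dpw
            if k >= 2:
                M[row, b_col(k)] = sk * diw
            M[row, a_col(k + 1)] = -sk1 * dpw
            M[row, b_col(k + 1)] = -sk1 * diw
            rhs[row] = -sk * diw if k == 1 else 0.0
            row += 1
        # insulating scalp surface at r = 1
        M[row, a_col(n_shells)] = n
        M[row, b_col(n_shells)] = -(n + 1)
        rhs[row] = 0.0

        sol = np.linalg.solve(M, rhs)
        t[n - 1] = sol[a_col(n_shells)] + sol[b_col(n_shells)]
    return t


def build_spherical_lead_field(
    sensors: SensorArray,
    patches: CorticalPatchModel,
    radii=DEFAULT_RADII_MM,
    conductivities: ConductivityProfile | None = None,
    n_terms: int = 60,
) -> LeadField:
    """Analytic lead field of a four-shell spherical head.

    Each patch is a unit dipole with the patch's fixed orientation; sensor
    positions are projected radially onto the scalp sphere.  The scalp
    potential is a Legendre series truncated at ``n_terms``; a
    :class:`~bandloc.errors.ConvergenceError` is raised when the last
    retained order still changes the worst-case patch by more than 1e-8
    relative.
    """
    conductivities = conductivities or ConductivityProfile()
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or len(radii) < 1:
        raise GeometryError("radii must be a 1-D sequence")
    if np.any(np.diff(radii) <= 0):
        raise GeometryError("shell radii must be strictly increasing (inner to outer)")
    sigmas = conductivities.shells_inner_to_outer()[: len(radii)]
    scalp_r = radii[-1]

    b = np.linalg.norm(patches.centers, axis=1)
    if np.any(b >= radii[0]):
        bad = int(np.argmax(b))
        raise GeometryError(
            f"patch {bad} at radius {b[bad]:.1f} mm is outside the innermost "
            f"shell ({radii[0]:.1f} mm)"
        )

    # project sensors onto the scalp sphere
    snorm = np.linalg.norm(sensors.positions, axis=1)
    if np.any(snorm == 0):
        raise GeometryError("sensor at the origin cannot be projected to the scalp")
    s_hat = sensors.positions / snorm[:, None]  # (ns, 3)

    t_n = _shell_transfer(n_terms, radii, sigmas)

    # dipole geometry, vectorized over sensors × patches
    eps = 1e-12
    b_scaled = b / scalp_r
    r0_hat = np.where(
        b[:, None] > eps,
        patches.centers / np.maximum(b, eps)[:, None],
        patches.orientations,  # direction is irrelevant at the center; see below
    )
    q = patches.orientations
    u = s_hat @ r0_hat.T                     # (ns, np) cos(angle sensor, patch)
    u = np.clip(u, -1.0, 1.0)
    q_r0 = np.einsum("pi,pi->p", q, r0_hat)  # q · r̂0, (np,)
    q_s = s_hat @ q.T                        # q · ŝ, (ns, np)

    # Legendre recurrences for P_n(u) and P_n'(u)
    ns, npts = u.shape
    V = np.zeros((ns, npts))
    p_prev = np.ones_like(u)     # P_0
    p_cur = u.copy()             # P_1
    dp_prev = np.zeros_like(u)   # P_0'
    dp_cur = np.ones_like(u)     # P_1'
    b_pow = np.ones(npts)        # b_scaled^(n-1)
    last_term_rel = np.zeros(npts)
    for n in range(1, n_terms + 1):
        term = t_n[n - 1] * b_pow * (
            n * p_cur * q_r0[None, :] + dp_cur * (q_s - u * q_r0[None, :])
        )
        V += term
        term_mag = np.max(np.abs(term), axis=0)
        if n == n_terms:
            scale = np.maximum(np.max(np.abs(V), axis=0), 1e-300)
            last_term_rel = term_mag / scale
        if n < n_terms:
            p_next = ((2 * n + 1) * u * p_cur - n * p_prev) / (n + 1)
            dp_next = dp_prev + (2 * n + 1) * p_cur
            p_prev, p_cur = p_cur, p_next
            dp_prev, dp_cur = dp_cur, dp_next
            b_pow = b_pow * b_scaled

    worst = float(np.max(last_term_rel)) if npts else 0.0
    if worst > 1e-8:
        raise ConvergenceError(
            f"Legendre series not converged at n_terms={n_terms}: worst "
            f"last-term relative contribution {worst:.2e} > 1e-8; increase "
            f"n_terms or use deeper sources"
        )

    # unit dipole moment = 1 nA·m; radii in mm -> meters; potential in µV
    scalp_m = scalp_r * 1e-3
    scale = 1e-9 / (4.0 * np.pi * sigmas[0] * scalp_m**2) * 1e6
    return LeadField(V * scale, reference="raw", sensors=sensors, patches=patches)


def single_sphere_potential_oracle(
    sensor_pos: np.ndarray,
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    radius_mm: float,
    sigma: float,
    moment_scale: float = 1e-9,
    eps_mm: float = 1e-2,
) -> np.ndarray:
    """Closed-form surface potential of a dipole in a homogeneous sphere (µV).

    Independent oracle: the dipole is represented as two closed-form current
    monopoles separated by ``eps_mm`` along the moment, using the summed
    generating functions of the Legendre series for a monopole in an
    insulated sphere.  No truncated series is involved.
    """
    sensor_pos = np.asarray(sensor_pos, dtype=float)
    s_hat = sensor_pos / np.linalg.norm(sensor_pos, axis=1, keepdims=True)
    q = np.asarray(dipole_moment, dtype=float)
    qn = np.linalg.norm(q)
    if qn == 0:
        return np.zeros(sensor_pos.shape[0])
    step = 0.5 * eps_mm * q / qn

    def v_monopole(r0):
        x = np.linalg.norm(r0) / radius_mm
        u = s_hat @ (r0 / max(np.linalg.norm(r0), 1e-300))
        u = np.clip(u, -1, 1)
        chi = np.sqrt(1.0 - 2.0 * x * u + x * x)
        # sum_{n>=1} (2n+1)/n x^n P_n(u) = 2(1/chi - 1) + ln(2/(1 - x u + chi))
        return 2.0 * (1.0 / chi - 1.0) + np.log(2.0 / (1.0 - x * u + chi))

    r_m = radius_mm * 1e-3
    # current-source strength I = |m| / eps so that I * eps = |m|
    i_amp = (qn * moment_scale) / (eps_mm * 1e-3)
    v = (v_monopole(dipole_pos + step) - v_monopole(dipole_pos - step)) * (
        i_amp / (4.0 * np.pi * sigma * r_m)
    )
    return v * 1e6  # µV


# ---------------------------------------------------------------------------
# file IO and referencing
# ---------------------------------------------------------------------------

def save_lead_field(lf: LeadField, path) -> None:
    """Persist to HDF5: dataset ``leadfield`` + dimension/reference attributes."""
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("leadfield", data=lf.matrix)
        ds.attrs["n_sensors"] = lf.n_sensors
        ds.attrs["n_patches"] = lf.n_patches
        ds.attrs["reference"] = lf.reference


def load_lead_field(path, sensors: SensorArray, patches: CorticalPatchModel) -> LeadField:
    """Load a dense sensors × patches matrix from HDF5 or delimited text.

    Dimensions are validated against the supplied sensor array and patch
    model; the reference tag is read from metadata and defaults to raw.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        with h5py.File(path, "r") as fh:
            ds = fh["leadfield"]
            matrix = ds[()]
            reference = ds.attrs.get("reference", "raw")
            if isinstance(reference, bytes):
                reference = reference.decode()
    else:
        matrix = np.loadtxt(path)
        reference = "raw"
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape != (sensors.n_sensors, patches.n_patches):
        raise FormatError(
            f"lead field is {matrix.shape}, expected "
            f"({sensors.n_sensors}, {patches.n_patches})"
        )
    if not np.all(np.isfinite(matrix)):
        raise FormatError("lead field contains non-finite entries")
    return LeadField(matrix, reference=reference, sensors=sensors, patches=patches)


def apply_common_average(lf: LeadField) -> LeadField:
    """Subtract each column's mean across sensors (common-average reference).

    The inverse operator must see a lead field in the same reference as the
    data; applying twice is a no-op and only triggers a warning.
    """
    if lf.reference == "common-average":
        warnings.warn("lead field already common-average referenced; returning input")
        return lf
    centered = lf.matrix - lf.matrix.mean(axis=0, keepdims=True)
    return LeadField(centered, reference="common-average",
                     sensors=lf.sensors, patches=lf.patches)
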