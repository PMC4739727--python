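"""Macroscopic gel model coupled to fiber-network RVEs.

The gel is a regular grid of trilinear hexahedral elements.  At each network
quadrature point sits a fiber-network RVE whose boundary is driven affinely
by the local macroscopic deformation gradient; the macroscopic Cauchy stress
is the symmetrized boundary dyadic average of the equilibrated network plus a
compressible neo-Hookean term

    sigma_nH = G/J (B - I) + 2 G nu / (J (1 - 2 nu)) ln(J) I

(B the left Cauchy-Green tensor, J = det F) that limits network distortion
and compressibility.  Fibroblast explants are represented by a *cellular*
element domain whose networks have their fiber reference lengths shortened
incrementally — the traction source — while the surrounding *ECM* domain
responds passively.

Two boundary-condition cases mirror the experiment: *Fixed* (all faces but
the top clamped to the mold) and *Free* (only a small centered square on the
bottom face anchored to the substrate).

Units: lengths in mm, stresses in Pa, fiber forces in N.  The RVE-local to
physical conversion is the single factor ``1 / rve_side**2`` (``rve_side`` in
meters) applied to the boundary dyadic sum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import spsolve
from shapely.geometry import Polygon
from shapely.ops import unary_union

from . import rve_network as rvn
from .rve_network import FiberNetwork, NetworkMaterial, SolverError

logger = logging.getLogger(__name__)

__all__ = [
    "HexMesh",
    "ExplantLayout",
    "DomainLabels",
    "ContinuumMaterial",
    "BoundaryCondition",
    "SimulationConfig",
    "MultiscaleModel",
    "CompactionResult",
    "build_mesh",
    "assign_domains",
    "reference_layout",
    "desk_layout",
    "fixed_bc",
    "free_bc",
    "neo_hookean_stress",
    "run_compaction",
    "reference_config",
    "desk_config",
    "element_regions",
    "write_vtk",
]

ECM, CELLULAR = 0, 1


# ---------------------------------------------------------------------------
# mesh and domains
# ---------------------------------------------------------------------------


@dataclass
class HexMesh:
    """Regular trilinear hexahedral grid over an Lx x Ly x Lz box (mm)."""

    coords: np.ndarray  # (n_nodes, 3)
    elements: np.ndarray  # (n_elements, 8) VTK hexahedron ordering
    nx: int
    ny: int
    nz: int
    Lx: float
    Ly: float
    Lz: float

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.Lx / self.nx, self.Ly / self.ny, self.Lz / self.nz

    def node_id(self, i, j, k):
        return i + (self.nx + 1) * (j + (self.ny + 1) * k)

    def element_id(self, i, j, k):
        return i + self.nx * (j + self.ny * k)

    def element_centroids(self) -> np.ndarray:
        return self.coords[self.elements].mean(axis=1)


def build_mesh(nx: int, ny: int, nz: int, Lx: float, Ly: float, Lz: float) -> HexMesh:
    """Regular grid mesh with ``nx*ny*nz`` elements over the given box."""
    if min(nx, ny, nz) < 1 or min(Lx, Ly, Lz) <= 0:
        raise ValueError("element counts must be >= 1 and dimensions positive")
    x = np.linspace(0.0, Lx, nx + 1)
    y = np.linspace(0.0, Ly, ny + 1)
    z = np.linspace(0.0, Lz, nz + 1)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    # node index = i + (nx+1)*(j + (ny+1)*k)
    coords = np.stack(
        [X.transpose(2, 1, 0).ravel(), Y.transpose(2, 1, 0).ravel(),
         Z.transpose(2, 1, 0).ravel()], axis=1
    )
    nid = lambda i, j, k: i + (nx + 1) * (j + (ny + 1) * k)
    elems = np.empty((nx * ny * nz, 8), dtype=np.int64)
    e = 0
    for k in range(nz):
        for j in range(ny):
            for i in range(nx):
                elems[nx * (j + ny * k) + i] = [
                    nid(i, j, k), nid(i + 1, j, k),
                    nid(i + 1, j + 1, k), nid(i, j + 1, k),
                    nid(i, j, k + 1), nid(i + 1, j, k + 1),
                    nid(i + 1, j + 1, k + 1), nid(i, j + 1, k + 1),
                ]
    return HexMesh(coords, elems, nx, ny, nz, float(Lx), float(Ly), float(Lz))


@dataclass
class ExplantLayout:
    """Explant patches on the top element layer.

    ``origins``: per-patch (i, j) element index of the patch lower-left
    corner; ``patch_size``: patch edge in elements (4 at full resolution).
    """

    origins: list[tuple[int, int]]
    patch_size: int = 4


@dataclass
class DomainLabels:
    """Cellular/ECM element partition with explant patch bookkeeping."""

    labels: np.ndarray  # (n_elements,) ECM=0, CELLULAR=1
    patches: list[np.ndarray]  # element ids per explant patch
    patch_centroids: np.ndarray  # (n_patches, 2) reference centroids (mm)

    @property
    def cellular_elements(self) -> np.ndarray:
        return np.flatnonzero(self.labels == CELLULAR)

    @property
    def ecm_elements(self) -> np.ndarray:
        return np.flatnonzero(self.labels == ECM)

    def centroid_distances(self) -> np.ndarray:
        """Pairwise centroid-to-centroid distances (p0-p1, p0-p2, p1-p2)."""
        c = self.patch_centroids
        return np.array(
            [np.linalg.norm(c[a] - c[b]) for a, b in ((0, 1), (0, 2), (1, 2))]
        )


def reference_layout() -> ExplantLayout:
    """Full-resolution layout: three 4x4 patches in a triangle.

    On the 46x46 grid the top pair of patch centroids sits 12 element widths
    apart (2.09 mm at 8 mm gel width) and the bottom patch (+/-6, -10)
    element widths from each (2.03 mm), with patch area 16 (Lx/nx)^2 =
    0.484 mm^2.
    """
    return ExplantLayout(origins=[(15, 26), (27, 26), (21, 16)], patch_size=4)


def desk_layout() -> ExplantLayout:
    """Scaled-down triangular layout for the 12x12x1 desk mesh."""
    return ExplantLayout(origins=[(4, 8), (7, 8), (5, 5)], patch_size=1)


def assign_domains(mesh: HexMesh, layout: ExplantLayout) -> DomainLabels:
    """Partition elements into cellular explant patches and ECM."""
    hx, hy, _ = mesh.spacing
    labels = np.full(mesh.n_elements, ECM, dtype=np.int8)
    k_top = mesh.nz - 1
    patches, centroids = [], []
    for i0, j0 in layout.origins:
        if not (0 <= i0 and i0 + layout.patch_size <= mesh.nx
                and 0 <= j0 and j0 + layout.patch_size <= mesh.ny):
            raise ValueError(f"explant patch at ({i0}, {j0}) leaves the mesh")
        ids = np.array(
            [
                mesh.element_id(i, j, k_top)
                for j in range(j0, j0 + layout.patch_size)
                for i in range(i0, i0 + layout.patch_size)
            ]
        )
        if np.any(labels[ids] == CELLULAR):
            raise ValueError("explant patches overlap")
        labels[ids] = CELLULAR
        patches.append(ids)
        centroids.append(
            ((i0 + layout.patch_size / 2) * hx, (j0 + layout.patch_size / 2) * hy)
        )
    return DomainLabels(labels, patches, np.array(centroids))


# ---------------------------------------------------------------------------
# materials and boundary conditions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContinuumMaterial:
    """Compressible neo-Hookean parameters: shear modulus G [Pa], nu [-]."""

    G: float = 1.0
    nu: float = 0.3

    def __post_init__(self):
        if not self.G > 0:
            raise ValueError("shear modulus must be positive")
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("Poisson's ratio must lie in [0, 0.5)")


def neo_hookean_stress(deformation_gradient: np.ndarray,
                       material: ContinuumMaterial) -> np.ndarray:
    """Compressible neo-Hookean Cauchy stress for a deformation gradient."""
    F = np.asarray(deformation_gradient, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0:
        raise ValueError("inverted element: det(F) <= 0")
    B = F @ F.T
    G, nu = material.G, material.nu
    return G / J * (B - np.eye(3)) + (
        2.0 * G * nu / (J * (1.0 - 2.0 * nu)) * math.log(J) * np.eye(3)
    )


@dataclass
class BoundaryCondition:
    """Dirichlet node set for the *Fixed* or *Free* experimental case."""

    case: str  # "fixed" | "free"
    fixed_nodes: np.ndarray
    anchor_mm: float | None = None


def fixed_bc(mesh: HexMesh) -> BoundaryCondition:
    """All faces clamped except the top surface (gel attached to the mold)."""
    c = mesh.coords
    tol = 1e-9
    on = (
        (c[:, 2] < tol)
        | (c[:, 0] < tol) | (c[:, 0] > mesh.Lx - tol)
        | (c[:, 1] < tol) | (c[:, 1] > mesh.Ly - tol)
    )
    return BoundaryCondition("fixed", np.flatnonzero(on))


def free_bc(mesh: HexMesh, anchor_mm: float = 1.74) -> BoundaryCondition:
    """Only bottom-face nodes within a centered anchor square clamped."""
    c = mesh.coords
    tol = 1e-9
    half = anchor_mm / 2.0
    on = (
        (c[:, 2] < tol)
        & (np.abs(c[:, 0] - mesh.Lx / 2) <= half + tol)
        & (np.abs(c[:, 1] - mesh.Ly / 2) <= half + tol)
    )
    idx = np.flatnonzero(on)
    if len(idx) == 0:
        raise ValueError("anchor square captures no bottom nodes")
    return BoundaryCondition("free", idx, anchor_mm)


# ---------------------------------------------------------------------------
# element quadrature tables (regular box elements)
# ---------------------------------------------------------------------------

_XI_CORNERS = np.array(
    [
        [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
        [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
    ],
    dtype=float,
)


def _shape(xi):
    """Trilinear shape functions at reference point xi (8,)."""
    return 0.125 * np.prod(1.0 + _XI_CORNERS * xi, axis=1)


def _dshape(xi):
    """Reference-coordinate gradients dN/dxi at xi (8, 3)."""
    out = np.empty((8, 3))
    for d in range(3):
        terms = 1.0 + _XI_CORNERS * xi
        terms[:, d] = _XI_CORNERS[:, d]
        out[:, d] = 0.125 * np.prod(terms, axis=1)
    return out


_G = 1.0 / math.sqrt(3.0)
FULL_GAUSS = [np.array(p) for p in
              [(-_G, -_G, -_G), (_G, -_G, -_G), (_G, _G, -_G), (-_G, _G, -_G),
               (-_G, -_G, _G), (_G, -_G, _G), (_G, _G, _G), (-_G, _G, _G)]]
CENTROID_GAUSS = [np.zeros(3)]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Full description of a compaction run (geometry through schedule)."""

    nx: int = 12
    ny: int = 12
    nz: int = 1
    Lx: float = 8.0
    Ly: float = 8.0
    Lz: float = 0.8
    patch_size: int = 1
    patch_origins: list = field(default_factory=lambda: [(4, 8), (7, 8), (5, 5)])
    bc_case: str = "free"
    anchor_mm: float = 1.74
    EfAf: float = 3e-10
    B: float = 4.0
    G: float = 1.0
    nu: float = 0.3
    target_fibers: int = 60
    density_param: float | None = None
    rves_per_element: int = 1
    rve_side: float = 20e-6  # meters; Pa = N / m^2 conversion of Eq-2 sum
    total_shortening: float = 0.24
    n_increments: int = 8
    seed: int = 0
    include_coupling: bool = False
    macro_rtol: float = 1e-4
    macro_atol: float = 1e-12
    macro_max_iter: int = 30
    rve_rel_tol: float = 1e-8

    def to_dict(self) -> dict:
        d = asdict(self)
        d["patch_origins"] = [list(p) for p in d["patch_origins"]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "patch_origins" in d:
            d["patch_origins"] = [tuple(p) for p in d["patch_origins"]]
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f))


def reference_config(bc_case: str = "fixed", **overrides) -> SimulationConfig:
    """The full-resolution configuration of the gel experiment (46x46x4 mesh,
    8 RVEs per element, 337-fiber networks, 24 increments to 24%)."""
    lay = reference_layout()
    cfg = SimulationConfig(
        nx=46, ny=46, nz=4, Lx=8.0, Ly=8.0, Lz=0.8,
        patch_size=lay.patch_size, patch_origins=list(lay.origins),
        bc_case=bc_case, target_fibers=337, rves_per_element=8,
        n_increments=24,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def desk_config(bc_case: str = "free", **overrides) -> SimulationConfig:
    """Scaled-down configuration (12x12x1 mesh, ~60-fiber networks, one RVE
    per element) preserving the geometry ratios for qualitative studies."""
    cfg = SimulationConfig(bc_case=bc_case)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------------------
# the coupled model
# ---------------------------------------------------------------------------


@dataclass
class _RVESlot:
    element: int
    gp: int
    seed: int
    cellular: bool
    network: FiberNetwork | None = None  # generated lazily
    positions: np.ndarray | None = None  # warm-start interior state
    solution: rvn.RVESolution | None = None
    normals: np.ndarray | None = None  # outward face normals at boundary nodes


class MultiscaleModel:
    """Coupled macro-micro gel model with incremental explant traction.

    Builds the mesh, domain partition and RVE grid from a
    :class:`SimulationConfig`; :meth:`run` performs the compaction schedule.
    Networks are generated lazily per quadrature slot from per-slot seeds, so
    constructing the model (and counting RVE slots) is cheap.
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        self.mesh = build_mesh(config.nx, config.ny, config.nz,
                               config.Lx, config.Ly, config.Lz)
        layout = ExplantLayout(list(config.patch_origins), config.patch_size)
        self.labels = assign_domains(self.mesh, layout)
        if config.bc_case == "fixed":
            self.bc = fixed_bc(self.mesh)
        elif config.bc_case == "free":
            self.bc = free_bc(self.mesh, config.anchor_mm)
        else:
            raise ValueError(f"unknown boundary-condition case {config.bc_case!r}")
        self.net_material = NetworkMaterial(config.EfAf, config.B)
        self.cont_material = ContinuumMaterial(config.G, config.nu)
        self.stress_scale = 1.0 / config.rve_side**2  # Pa per (N / local area)

        if config.rves_per_element == 1:
            self.net_gauss = CENTROID_GAUSS
            self.net_weights = [8.0]
        elif config.rves_per_element == 8:
            self.net_gauss = FULL_GAUSS
            self.net_weights = [1.0] * 8
        else:
            raise ValueError("rves_per_element must be 1 or 8")

        self.slots: list[_RVESlot] = []
        cell = set(self.labels.cellular_elements.tolist())
        for e in range(self.mesh.n_elements):
            for g in range(len(self.net_gauss)):
                ss = np.random.SeedSequence([int(config.seed), e, g])
                seed = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
                self.slots.append(_RVESlot(e, g, seed, e in cell))
        self._slot_of = {(s.element, s.gp): s for s in self.slots}

        self.u = np.zeros((self.mesh.n_nodes, 3))
        self.compaction = 0.0
        self.residual_log: list[list[float]] = []
        self.asymmetry_log: list[float] = []
        self.coupling_log: list[float] = []

        # precomputed element tables
        hx, hy, hz = self.mesh.spacing
        self._jac = np.array([hx / 2, hy / 2, hz / 2])
        self._detJ = hx * hy * hz / 8.0
        self._gradN_net = [_dshape(xi) / self._jac for xi in self.net_gauss]
        self._gradN_nh = [_dshape(xi) / self._jac for xi in FULL_GAUSS]
        self._shape_net = [_shape(xi) for xi in self.net_gauss]
        free = np.ones(self.mesh.n_nodes, dtype=bool)
        free[self.bc.fixed_nodes] = False
        self._free_dof = np.flatnonzero(np.repeat(free, 3))

    # -- RVE plumbing ------------------------------------------------------

    @property
    def n_rves(self) -> int:
        """Number of RVE slots (8,464 elements x 8 = 67,712 at full scale)."""
        return len(self.slots)

    def network_for(self, slot: _RVESlot) -> FiberNetwork:
        if slot.network is None:
            slot.network = rvn.generate_network(
                slot.seed,
                target_fibers=self.config.target_fibers,
                density_param=self.config.density_param,
            )
            pos = slot.network.node_positions
            b = slot.network.boundary_idx
            normals = np.zeros((len(b), 3))
            for axis in range(3):
                normals[pos[b][:, axis] < 1e-9, axis] -= 1.0
                normals[pos[b][:, axis] > 1 - 1e-9, axis] += 1.0
            norms = np.linalg.norm(normals, axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            slot.normals = normals / norms
        return slot.network

    def _solve_slot(self, slot: _RVESlot, F: np.ndarray):
        net = self.network_for(slot)
        c = np.full(3, 0.5)
        xb = net.node_positions[net.boundary_idx]
        bd = (xb - c) @ F.T + c - xb
        sol = rvn.solve_equilibrium(
            net, bd, self.net_material,
            rel_tol=self.config.rve_rel_tol, max_iter=80,
            x0=slot.positions,
        )
        slot.positions = sol.deformed_positions
        slot.solution = sol
        return sol

    def _slot_stress(self, slot: _RVESlot, F: np.ndarray):
        """Cauchy stress contributions at a network quadrature point.

        Returns (sigma_total, S_sym, J, F_inv_T) with sigma in Pa; the
        network part divides the boundary dyadic sum by current RVE volume
        J * V0 and applies the physical scale factor.
        """
        sol = self._solve_slot(slot, F)
        net = slot.network
        S = rvn.volume_avg_stress(sol, net, scale=1.0)
        asym = np.linalg.norm(S - S.T) / max(np.linalg.norm(S), 1e-300)
        self._asym_max = max(getattr(self, "_asym_max", 0.0), asym)
        S_sym = 0.5 * (S + S.T)
        J = float(np.linalg.det(F))
        if J <= 0:
            raise SolverError(f"inverted element {slot.element} (J={J:.3e})")
        sigma = self.stress_scale * S_sym / J + neo_hookean_stress(F, self.cont_material)
        return sigma, S_sym, J

    # -- assembly ----------------------------------------------------------

    def _element_F(self, e: int, gradN, u=None):
        u = self.u if u is None else u
        ue = u[self.mesh.elements[e]]  # (8,3)
        return np.eye(3) + ue.T @ gradN

    def _residual(self, u) -> np.ndarray:
        """Global internal-force vector (no external loads)."""
        mesh = self.mesh
        r = np.zeros((mesh.n_nodes, 3))
        for e in range(mesh.n_elements):
            conn = mesh.elements[e]
            fe = np.zeros((8, 3))
            # network term at the network quadrature points
            for g, (gradN, w) in enumerate(zip(self._gradN_net, self.net_weights)):
                F = self._element_F(e, gradN, u)
                slot = self._slot_of[(e, g)]
                sol = self._solve_slot(slot, F)
                S = rvn.volume_avg_stress(sol, slot.network, scale=1.0)
                S_sym = 0.5 * (S + S.T)
                # P_net = J sigma F^-T = scale * S_sym F^-T  (J cancels)
                P = self.stress_scale * S_sym @ np.linalg.inv(F).T
                fe += w * self._detJ * gradN @ P.T
                if self.config.include_coupling:
                    fe -= w * self._detJ * np.outer(
                        self._shape_net[g], self._coupling_term(slot, F)
                    )
            # continuum term at full quadrature
            for gradN in self._gradN_nh:
                F = self._element_F(e, gradN, u)
                J = float(np.linalg.det(F))
                if J <= 0:
                    raise SolverError(f"inverted element {e} (J={J:.3e})")
                sig = neo_hookean_stress(F, self.cont_material)
                P = J * sig @ np.linalg.inv(F).T
                fe += self._detJ * gradN @ P.T
            np.add.at(r, conn, fe)
        return r

    def _coupling_term(self, slot: _RVESlot, F: np.ndarray) -> np.ndarray:
        """Discrete boundary-node estimate of the scale-coupling body force.

        Approximates (1/V) closed-surface integral of
        (sigma_ij - <sigma_ij>) u_k,i n_k dA by attributing tractions to
        boundary-node reactions: t_j = (1/V) sum_b f_j^b (n.grad(u).n)_b;
        the <sigma> part integrates to zero over the closed RVE surface.
        """
        sol, net = slot.solution, slot.network
        gradu = F - np.eye(3)
        n = slot.normals
        proj = np.einsum("bi,ik,bk->b", n, gradu, n)
        t = self.stress_scale / net.volume * (sol.boundary_forces * proj[:, None]).sum(0)
        ref = self.stress_scale * np.abs(sol.avg_stress).max() + 1e-300
        self._coupling_max = max(
            getattr(self, "_coupling_max", 0.0), float(np.abs(t).max() / ref)
        )
        return t

    def _tangent(self) -> sparse.csr_matrix:
        """Global consistent tangent (coupling term treated explicitly)."""
        mesh = self.mesh
        ndof = 3 * mesh.n_nodes
        rows, cols, vals = [], [], []
        eye = np.eye(3)
        h_fd = 1e-7
        for e in range(mesh.n_elements):
            conn = mesh.elements[e]
            dofs = (3 * conn[:, None] + np.arange(3)[None, :]).ravel()
            ke = np.zeros((24, 24))
            for g, (gradN, w) in enumerate(zip(self._gradN_net, self.net_weights)):
                F = self._element_F(e, gradN)
                slot = self._slot_of[(e, g)]
                sol = self._solve_slot(slot, F)
                A = rvn.stress_sensitivity(slot.network, sol, self.net_material)
                A = 0.5 * (A + A.transpose(1, 0, 2, 3))  # d(S_sym)/dF
                S = rvn.volume_avg_stress(sol, slot.network, scale=1.0)
                S_sym = 0.5 * (S + S.T)
                Fit = np.linalg.inv(F).T
                # dP/dF with P = scale * S_sym F^-T
                D = self.stress_scale * (
                    np.einsum("imkl,mJ->iJkl", A, Fit)
                    - np.einsum("im,ml,kJ->iJkl", S_sym, Fit, Fit)
                )
                kgp = np.einsum("iJkL,aJ,bL->aibk", D, gradN, gradN)
                ke += w * self._detJ * kgp.reshape(24, 24)
            for gradN in self._gradN_nh:
                F = self._element_F(e, gradN)
                P0 = _nominal_nh(F, self.cont_material)
                D = np.empty((3, 3, 3, 3))
                for k in range(3):
                    for l in range(3):
                        Fp = F.copy()
                        Fp[k, l] += h_fd
                        D[:, :, k, l] = (_nominal_nh(Fp, self.cont_material) - P0) / h_fd
                kgp = np.einsum("iJkL,aJ,bL->aibk", D, gradN, gradN)
                ke += self._detJ * kgp.reshape(24, 24)
            rows.append(np.repeat(dofs, 24))
            cols.append(np.tile(dofs, 24))
            vals.append(ke.ravel())
        K = sparse.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(ndof, ndof),
        )
        return K.tocsr()

    # -- solves ------------------------------------------------------------

    def macro_solve(self) -> None:
        """Newton-solve macroscopic equilibrium at the current compaction."""
        cfg = self.config
        free = self._free_dof
        self._asym_max = 0.0
        self._coupling_max = 0.0
        r = self._residual(self.u).ravel()[free]
        r0 = float(np.abs(r).max())
        history = [r0]
        if r0 <= cfg.macro_atol:
            self.residual_log.append(history)
            return
        tol = max(cfg.macro_atol, cfg.macro_rtol * r0)
        best_res, best_u = r0, self.u.copy()

        def _finish():
            self.residual_log.append(history)
            self.asymmetry_log.append(self._asym_max)
            if cfg.include_coupling:
                self.coupling_log.append(self._coupling_max)

        for _ in range(cfg.macro_max_iter):
            K = self._tangent()[free][:, free]
            du = spsolve(K.tocsc(), -r)
            if not np.all(np.isfinite(du)):
                raise SolverError("macro Newton produced non-finite step", history)
            alpha = 1.0
            res_now = float(np.abs(r).max())
            for _ in range(6):
                u_try = self.u.copy()
                u_try.reshape(-1)[free] += alpha * du
                try:
                    r_try = self._residual(u_try).ravel()[free]
                except SolverError:
                    alpha *= 0.5
                    continue
                if float(np.abs(r_try).max()) < res_now or alpha < 0.1:
                    self.u = u_try
                    r = r_try
                    break
                alpha *= 0.5
            else:
                raise SolverError(
                    "macro Newton diverged; consider cutting the increment",
                    history,
                )
            history.append(float(np.abs(r).max()))
            if history[-1] < best_res:
                best_res, best_u = history[-1], self.u.copy()
            if history[-1] <= tol:
                _finish()
                return
            # the micro solves have their own tolerance; once the macro
            # residual stops improving near that noise floor, accept the
            # best iterate rather than chase noise
            if (
                len(history) >= 6
                and min(history[-5:]) >= 0.8 * best_res
                and best_res <= max(cfg.macro_atol, 1e-3 * r0)
            ):
                self.u = best_u
                self._residual(self.u)  # restore RVE states at best iterate
                _finish()
                return
        raise SolverError(
            f"macro Newton: no convergence in {cfg.macro_max_iter} iterations "
            f"(residual history {history})",
            history,
        )

    def apply_shortening(self, fraction: float) -> None:
        """Shorten cellular-network reference lengths by ``fraction``."""
        for slot in self.slots:
            if slot.cellular:
                net = self.network_for(slot)
                slot.network = rvn.shorten_reference_lengths(net, fraction)
        self.compaction = 1.0 - (1.0 - self.compaction) * (1.0 - fraction)

    def step(self, fraction: float, _depth: int = 0) -> None:
        """One compaction increment with automatic increment cutting."""
        state = (self.u.copy(), self.compaction,
                 [(s.network, s.positions) for s in self.slots])
        try:
            self.apply_shortening(fraction)
            self.macro_solve()
        except SolverError:
            if _depth >= 3:
                raise
            self.u, self.compaction = state[0], state[1]
            for s, (net, pos) in zip(self.slots, state[2]):
                s.network, s.positions = net, pos
            half = 1.0 - math.sqrt(1.0 - fraction)
            logger.warning("cutting increment %.4f -> 2 x %.4f", fraction, half)
            self.step(half, _depth + 1)
            self.step(half, _depth + 1)

    # -- output quantities -------------------------------------------------

    def reaction_forces(self) -> np.ndarray:
        """Reactions at the Dirichlet nodes (internal force with sign flip)."""
        r = self._residual(self.u)
        out = np.zeros_like(r)
        out[self.bc.fixed_nodes] = -r[self.bc.fixed_nodes]
        return out

    def element_alpha(self) -> np.ndarray:
        """Per-element strength of alignment of the deformed networks."""
        out = np.zeros(self.mesh.n_elements)
        cnt = np.zeros(self.mesh.n_elements)
        for slot in self.slots:
            net = self.network_for(slot)
            pos = slot.positions if slot.positions is not None else net.node_positions
            res = rvn.network_orientation(net, pos)
            out[slot.element] += res.alpha
            cnt[slot.element] += 1
        return out / cnt

    def element_fiber_force(self) -> np.ndarray:
        """Per-element mean signed fiber force [N] (tension positive)."""
        out = np.zeros(self.mesh.n_elements)
        cnt = np.zeros(self.mesh.n_elements)
        for slot in self.slots:
            net = self.network_for(slot)
            pos = slot.positions if slot.positions is not None else net.node_positions
            vec = pos[net.fibers[:, 1]] - pos[net.fibers[:, 0]]
            lam = np.linalg.norm(vec, axis=1) / net.ref_lengths
            out[slot.element] += float(np.mean(rvn.fiber_force(lam, self.net_material)))
            cnt[slot.element] += 1
        return out / cnt

    def fiber_forces(self, elements=None) -> np.ndarray:
        """Concatenated fiber forces [N] over the given elements (default all)."""
        keep = set(range(self.mesh.n_elements)) if elements is None else set(
            np.asarray(elements).tolist()
        )
        forces = []
        for slot in self.slots:
            if slot.element not in keep:
                continue
            net = self.network_for(slot)
            pos = slot.positions if slot.positions is not None else net.node_positions
            vec = pos[net.fibers[:, 1]] - pos[net.fibers[:, 0]]
            lam = np.linalg.norm(vec, axis=1) / net.ref_lengths
            forces.append(rvn.fiber_force(lam, self.net_material))
        return np.concatenate(forces) if forces else np.zeros(0)

    def _patch_top_polygons(self) -> list:
        """Deformed top-face footprint polygon of each explant patch."""
        mesh = self.mesh
        x = mesh.coords + self.u
        polys = []
        for ids in self.labels.patches:
            quads = []
            for e in ids:
                top = mesh.elements[e][4:]  # top-face nodes, CCW
                quads.append(Polygon(x[top][:, :2]))
            polys.append(unary_union(quads))
        return polys

    def explant_areas(self) -> np.ndarray:
        """Deformed explant areas (mm^2) from top-surface patch polygons."""
        return np.array([p.area for p in self._patch_top_polygons()])

    def explant_centroids(self) -> np.ndarray:
        return np.array(
            [[p.centroid.x, p.centroid.y] for p in self._patch_top_polygons()]
        )

    def centroid_distances(self) -> np.ndarray:
        c = self.explant_centroids()
        return np.array(
            [np.linalg.norm(c[a] - c[b]) for a, b in ((0, 1), (0, 2), (1, 2))]
        )


def _nominal_nh(F, material) -> np.ndarray:
    J = float(np.linalg.det(F))
    if J <= 0:
        raise SolverError("inverted element in tangent evaluation")
    return J * neo_hookean_stress(F, material) @ np.linalg.inv(F).T


# ---------------------------------------------------------------------------
# compaction driver
# ---------------------------------------------------------------------------


@dataclass
class CompactionResult:
    """Output bundle of a compaction run."""

    config: SimulationConfig
    compaction: np.ndarray  # (n_steps + 1,) cumulative shortening fraction
    displacements: np.ndarray  # (n_steps + 1, n_nodes, 3) mm
    areas: np.ndarray  # (n_steps + 1, 3) mm^2
    centroid_dists: np.ndarray  # (n_steps + 1, 3) mm
    alpha0: np.ndarray  # per-element initial strength of alignment
    alpha: np.ndarray  # per-element final strength of alignment
    delta_alpha: np.ndarray
    mean_fiber_force: np.ndarray  # per-element mean force [N], final state
    fiber_forces_ecm: np.ndarray  # pooled ECM fiber forces [N], final state
    residual_log: list
    model: MultiscaleModel

    def area_ratios(self) -> np.ndarray:
        return self.areas / self.areas[0]

    def distance_ratios(self) -> np.ndarray:
        return self.centroid_dists / self.centroid_dists[0]

    def summary_frame(self) -> pd.DataFrame:
        steps = np.arange(len(self.compaction))
        return pd.DataFrame(
            {
                "step": steps,
                "compaction": self.compaction,
                "mean_area_mm2": self.areas.mean(axis=1),
                "area_ratio": self.area_ratios().mean(axis=1),
                "mean_centroid_dist_mm": self.centroid_dists.mean(axis=1),
                "distance_ratio": self.distance_ratios().mean(axis=1),
            }
        )


def run_compaction(config: SimulationConfig) -> CompactionResult:
    """Run the incremental compaction schedule and collect outputs.

    The total reference-length shortening is applied over ``n_increments``
    equal multiplicative steps (per-step factor ``(1 - total)^(1/n)``), with
    macroscopic equilibrium re-solved and outputs recorded after each.
    """
    model = MultiscaleModel(config)
    n = config.n_increments
    per_step = (
        0.0 if config.total_shortening == 0.0 or n == 0
        else 1.0 - (1.0 - config.total_shortening) ** (1.0 / n)
    )
    alpha0 = model.element_alpha()
    compaction = [0.0]
    disp = [model.u.copy()]
    areas = [model.explant_areas()]
    dists = [model.centroid_distances()]
    for _ in range(n):
        model.step(per_step)
        compaction.append(model.compaction)
        disp.append(model.u.copy())
        areas.append(model.explant_areas())
        dists.append(model.centroid_distances())
    alpha = model.element_alpha()
    return CompactionResult(
        config=config,
        compaction=np.array(compaction),
        displacements=np.array(disp),
        areas=np.array(areas),
        centroid_dists=np.array(dists),
        alpha0=alpha0,
        alpha=alpha,
        delta_alpha=alpha - alpha0,
        mean_fiber_force=model.element_fiber_force(),
        fiber_forces_ecm=model.fiber_forces(model.labels.ecm_elements),
        residual_log=model.residual_log,
        model=model,
    )


# ---------------------------------------------------------------------------
# regions and export
# ---------------------------------------------------------------------------


def element_regions(
    mesh: HexMesh,
    labels: DomainLabels,
    axial_halfwidth: float | None = None,
    near_radius: float | None = None,
) -> dict[str, np.ndarray]:
    """Geometric ECM element classes: near-explant, axial, far-field.

    Axial elements lie within ``axial_halfwidth`` of a centroid-to-centroid
    segment between explants; near-explant elements lie within
    ``near_radius`` of a patch centroid (the two classes may overlap);
    far-field elements are in neither.  Defaults scale with the explant
    spacing.
    """
    cent = mesh.element_centroids()[:, :2]
    pc = labels.patch_centroids
    spacing = np.mean(
        [np.linalg.norm(pc[a] - pc[b]) for a, b in ((0, 1), (0, 2), (1, 2))]
    )
    if axial_halfwidth is None:
        axial_halfwidth = 0.2 * spacing
    if near_radius is None:
        near_radius = 0.45 * spacing
    ecm = labels.labels == ECM

    def seg_dist(p, a, b):
        ab = b - a
        t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
        return np.linalg.norm(p - (a + t[:, None] * ab), axis=1)

    near = np.min([np.linalg.norm(cent - c, axis=1) for c in pc], axis=0) < near_radius
    axial = np.zeros(mesh.n_elements, dtype=bool)
    for a, b in ((0, 1), (0, 2), (1, 2)):
        axial |= seg_dist(cent, pc[a], pc[b]) < axial_halfwidth
    near &= ecm
    axial &= ecm
    far = ecm & ~near & ~axial
    return {"near": np.flatnonzero(near), "axial": np.flatnonzero(axial),
            "far": np.flatnonzero(far)}


def write_vtk(path, mesh: HexMesh, point_data=None, cell_data=None) -> None:
    """Write the mesh with nodal/element fields as legacy ASCII VTK."""
    point_data = point_data or {}
    cell_data = cell_data or {}
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nfibergel output\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.coords, fmt="%.9g")
        f.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}\n")
        np.savetxt(
            f,
            np.column_stack([np.full(mesh.n_elements, 8), mesh.elements]),
            fmt="%d",
        )
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(f, np.full(mesh.n_elements, 12), fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, arr, fmt="%.9g")
                else:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr.ravel(), fmt="%.9g")
        if cell_data:
            f.write(f"CELL_DATA {mesh.n_elements}\n")
            for name, arr in cell_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, np.asarray(arr).ravel(), fmt="%.9g")
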