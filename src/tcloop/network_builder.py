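"""Network construction: species, circuits, loops and the parameter cube.

The rodent network has six populations of 100 neurons (Ctx, TC, TRN for each
of the core and matrix circuits, 600 total); the primate adds a local
thalamic interneuron (IN) population per circuit (800 total).

Receptor logic follows the driving/modulatory division of labour between
circuits: in the core, corticothalamic (Ctx->TC) synapses are metabotropic
(mGluR) and thalamocortical (TC->Ctx) synapses ionotropic (AMPA); in the
matrix the arrangement is reversed (ionotropic NMDA down, metabotropic mGluR
up).  Thalamocortical projections are spatially spread with a Gaussian
(matrix an order of magnitude wider than core); every other connection is
one-to-one.

TRN-TC wiring comes in three motifs: closed (TRN_i inhibits TC_i which
reciprocally excites TRN_i), open (TRN_i inhibits TC_{i+offset} with no
reciprocal excitation) and hybrid (a deterministic interleave of the two).

A cube point (core_tc, matrix_tc, cc_mixing) multiplies the corresponding
thalamocortical and cortico-cortical edge weights; the control case is the
unit point, the starting case the all-low vertex.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .params import load_params

POP_SIZE = 100
EXCITATORY = ("AMPA", "NMDA", "mGluR")
INHIBITORY = ("GABA_A", "GABA_B")

# cube multipliers: low / control / high
CUBE_LOW, CUBE_CONTROL, CUBE_HIGH = 0.5, 1.0, 2.0


@dataclass(frozen=True)
class CubePoint:
    core_tc_strength: float = CUBE_CONTROL
    matrix_tc_strength: float = CUBE_CONTROL
    cc_mixing_strength: float = CUBE_CONTROL

    def __post_init__(self):
        for v in (self.core_tc_strength, self.matrix_tc_strength,
                  self.cc_mixing_strength):
            if not np.isfinite(v) or v < 0:
                raise ValueError("cube coordinates must be finite and >= 0")

    @staticmethod
    def starting_case() -> "CubePoint":
        return CubePoint(CUBE_LOW, CUBE_LOW, CUBE_LOW)

    @staticmethod
    def control_case() -> "CubePoint":
        return CubePoint(CUBE_CONTROL, CUBE_CONTROL, CUBE_CONTROL)

    @staticmethod
    def vertices() -> list["CubePoint"]:
        """The eight corners of the parameter cube."""
        vals = (CUBE_LOW, CUBE_HIGH)
        return [CubePoint(x, y, z) for x in vals for y in vals for z in vals]


@dataclass
class ProjectionKernel:
    weights: np.ndarray           # over offsets -R..R, unit sum
    sigma_center: float
    sigma_surround: float | None = None
    kind: str = "gaussian"

    @property
    def radius(self) -> int:
        return (len(self.weights) - 1) // 2


def make_kernel(circuit: str, base_sigma: float = 1.0,
                kind: str = "gaussian", surround_ratio: float = 2.0,
                surround_amplitude: float = 0.5) -> ProjectionKernel:
    """Spatial spread of a thalamocortical projection, in neuron-index units.

    Matrix projections are an order of magnitude (10x) wider than core.
    """
    if base_sigma <= 0:
        raise ValueError("base_sigma must be positive")
    if circuit not in ("core", "matrix"):
        raise ValueError(f"unknown circuit {circuit!r}")
    sigma = base_sigma * (10.0 if circuit == "matrix" else 1.0)
    radius = max(1, int(np.ceil(4.0 * sigma * max(1.0, surround_ratio
                                                  if kind != "gaussian" else 1.0))))
    x = np.arange(-radius, radius + 1, dtype=float)
    w = np.exp(-0.5 * (x / sigma) ** 2)
    sigma_surround = None
    if kind == "difference_of_gaussians":
        sigma_surround = sigma * surround_ratio
        w = w - surround_amplitude * np.exp(-0.5 * (x / sigma_surround) ** 2)
    elif kind != "gaussian":
        raise ValueError(f"unknown kernel kind {kind!r}")
    w = w / w.sum()
    return ProjectionKernel(weights=w, sigma_center=sigma,
                            sigma_surround=sigma_surround, kind=kind)


def kernel_matrix(kernel: ProjectionKernel, n_post: int, n_pre: int) -> np.ndarray:
    """Zero-padded (clip) convolution matrix W[i, j] = k[i - j]."""
    W = np.zeros((n_post, n_pre))
    w, R = kernel.weights, kernel.radius
    for off in range(-R, R + 1):
        idx_post = np.arange(max(0, off), min(n_post, n_pre + off))
        W[idx_post, idx_post - off] = w[off + R]
    return W


def wire_loop(loop: str, n: int, open_offset: int = 5,
              closed_fraction: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """(TRN->TC, TC->TRN) 0/1 adjacency for one circuit's loop motif."""
    if n < 2:
        raise ValueError("need at least 2 neurons")
    eye = np.eye(n)
    if loop == "closed":
        return eye.copy(), eye.copy()
    shifted = np.zeros((n, n))
    shifted[(np.arange(n) + open_offset) % n, np.arange(n)] = 1.0
    if loop == "open":
        return shifted, eye.copy()
    if loop == "hybrid":
        f = closed_fraction
        closed_mask = np.floor((np.arange(n) + 1) * f) - np.floor(np.arange(n) * f) >= 1
        trn_tc = np.zeros((n, n))
        for i in range(n):
            if closed_mask[i]:
                trn_tc[i, i] = 1.0
            else:
                trn_tc[(i + open_offset) % n, i] = 1.0
        return trn_tc, eye.copy()
    raise ValueError(f"unknown loop {loop!r}")


@dataclass
class PopulationSpec:
    name: str
    kind: str       # Ctx | TC | TRN | IN
    circuit: str    # core | matrix
    size: int = POP_SIZE


@dataclass
class ConnectionSpec:
    source: str
    target: str
    receptor: str
    weight: float                       # total conductance onto one target (mS/cm^2)
    matrix: np.ndarray                  # (n_target, n_source) unit-normalized adjacency
    kernel: ProjectionKernel | None = None

    @property
    def is_metabotropic(self) -> bool:
        return self.receptor in ("GABA_B", "mGluR")


# default per-projection total conductances (mS/cm^2 of postsynaptic membrane);
# cube multipliers scale the thalamocortical and cortico-cortical entries
DEFAULT_WEIGHTS = {
    "tc_ctx": 1.0,      # thalamocortical, scaled by circuit strength
    "ctx_tc": 0.05,     # corticothalamic
    "tc_trn": 0.6,      # relay drive onto TRN
    "ctx_trn": 0.1,     # corticothalamic collateral onto TRN
    "trn_tc": 0.5,      # reticular inhibition of relay cells (GABA_A)
    "trn_tc_b": 0.005,  # slow reticular inhibition (GABA_B) riding on the same edges
    "ctx_ctx": 0.05,    # cortico-cortical mixing, scaled by cc strength
    "tc_in": 0.10,      # relay drive onto interneurons (primate)
    "in_tc": 0.10,      # feed-forward interneuron inhibition (primate)
}

# control-case calibration: per-(species, loop) adjustments applied on top of
# DEFAULT_WEIGHTS.  The control case is the balanced-activity operating point
# between inactivity and saturation, calibrated per configuration (the loop
# wiring changes how much drive a circuit needs to spread without locking up).
CONTROL_CALIBRATION: dict[tuple[str, str], dict] = {
    ("rodent", "closed"): {},
    ("rodent", "open"): {"tc_ctx": 0.9},
    ("rodent", "hybrid"): {"tc_ctx": 1.3},
    ("primate", "closed"): {"tc_ctx": 1.1, "in_tc": 0.05},
    ("primate", "open"): {"tc_ctx": 1.1, "in_tc": 0.05},
    ("primate", "hybrid"): {"tc_ctx": 1.3, "in_tc": 0.05, "tc_in": 0.3},
}

# receptor class per circuit: (Ctx->TC, TC->Ctx); core is metabotropic down /
# ionotropic up, matrix the reverse
_CIRCUIT_RECEPTORS = {
    "core": ("mGluR", "AMPA"),
    "matrix": ("NMDA", "mGluR"),
}


@dataclass
class NetworkConfig:
    species: str
    loop: str
    cube: CubePoint
    populations: list[PopulationSpec]
    connections: list[ConnectionSpec]
    params: dict = field(default_factory=dict)
    open_offset: int = 5
    closed_fraction: float = 0.5

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.populations)

    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(name)

    def population_slice(self, name: str) -> slice:
        start = 0
        for p in self.populations:
            if p.name == name:
                return slice(start, start + p.size)
            start += p.size
        raise KeyError(name)

    def edge_list_csv(self) -> str:
        """Export every edge as CSV (source_pop, source_idx, target_pop, target_idx, receptor, weight)."""
        buf = io.StringIO()
        buf.write("source_pop,source_idx,target_pop,target_idx,receptor,weight\n")
        for c in self.connections:
            tgt, src = np.nonzero(c.matrix)
            for t, s in zip(tgt, src):
                buf.write(f"{c.source},{s},{c.target},{t},{c.receptor},"
                          f"{c.weight * c.matrix[t, s]:.6g}\n")
        return buf.getvalue()


def build_network(species: str, loop: str, cube: CubePoint | None = None,
                  params: dict | None = None,
                  weights: dict | None = None,
                  open_offset: int = 5, closed_fraction: float = 0.5,
                  base_sigma: float = 1.0,
                  kernel_kind: str = "gaussian",
                  pop_size: int = POP_SIZE) -> NetworkConfig:
    """Assemble the full species- and loop-specific connectivity graph."""
    if species not in ("rodent", "primate"):
        raise ValueError(f"unknown species {species!r}")
    if loop not in ("closed", "open", "hybrid"):
        raise ValueError(f"unknown loop {loop!r}")
    cube = cube or CubePoint.control_case()
    params = params if params is not None else load_params()
    w = dict(DEFAULT_WEIGHTS)
    w.update(CONTROL_CALIBRATION.get((species, loop), {}))
    if weights:
        unknown = set(weights) - set(w)
        if unknown:
            raise ValueError(f"unknown weight keys {sorted(unknown)}")
        w.update(weights)

    kinds = ["Ctx", "TC", "TRN"] + (["IN"] if species == "primate" else [])
    populations = [PopulationSpec(f"{kind}_{circ}", kind, circ, pop_size)
                   for circ in ("core", "matrix") for kind in kinds]

    n = pop_size
    eye = np.eye(n)
    connections: list[ConnectionSpec] = []

    for circ, tc_strength in (("core", cube.core_tc_strength),
                              ("matrix", cube.matrix_tc_strength)):
        down_rec, up_rec = _CIRCUIT_RECEPTORS[circ]
        kern = make_kernel(circ, base_sigma, kernel_kind)
        W_tc_ctx = kernel_matrix(kern, n, n)
        connections.append(ConnectionSpec(
            f"TC_{circ}", f"Ctx_{circ}", up_rec,
            w["tc_ctx"] * tc_strength, W_tc_ctx, kernel=kern))
        connections.append(ConnectionSpec(
            f"Ctx_{circ}", f"TC_{circ}", down_rec, w["ctx_tc"], eye.copy()))

        trn_tc, tc_trn = wire_loop(loop, n, open_offset, closed_fraction)
        connections.append(ConnectionSpec(
            f"TRN_{circ}", f"TC_{circ}", "GABA_A", w["trn_tc"], trn_tc))
        if w["trn_tc_b"] > 0:
            connections.append(ConnectionSpec(
                f"TRN_{circ}", f"TC_{circ}", "GABA_B", w["trn_tc_b"], trn_tc.copy()))
        connections.append(ConnectionSpec(
            f"TC_{circ}", f"TRN_{circ}", "AMPA", w["tc_trn"], tc_trn))
        connections.append(ConnectionSpec(
            f"Ctx_{circ}", f"TRN_{circ}", "AMPA", w["ctx_trn"], eye.copy()))

        if species == "primate":
            connections.append(ConnectionSpec(
                f"TC_{circ}", f"IN_{circ}", "AMPA", w["tc_in"], eye.copy()))
            connections.append(ConnectionSpec(
                f"IN_{circ}", f"TC_{circ}", "GABA_A", w["in_tc"], eye.copy()))

    cc = w["ctx_ctx"] * cube.cc_mixing_strength
    connections.append(ConnectionSpec("Ctx_core", "Ctx_matrix", "AMPA", cc, eye.copy()))
    connections.append(ConnectionSpec("Ctx_matrix", "Ctx_core", "AMPA", cc, eye.copy()))

    return NetworkConfig(species=species, loop=loop, cube=cube,
                         populations=populations, connections=connections,
                         params=params, open_offset=open_offset,
                         closed_fraction=closed_fraction)


def reciprocal_pairs(net: NetworkConfig, circuit: str = "core") -> int:
    """Count TRN_i -> TC_j edges whose mirror TC_j -> TRN_i edge exists."""
    trn_tc = next(c for c in net.connections
                  if c.source == f"TRN_{circuit}" and c.target == f"TC_{circuit}")
    tc_trn = next(c for c in net.connections
                  if c.source == f"TC_{circuit}" and c.target == f"TRN_{circuit}")
    return int(np.sum((trn_tc.matrix > 0) & (tc_trn.matrix.T > 0)))
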