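"""Synthetic fixtures: toy protein-DNA complexes and feature tables.

Two generators make every stage of the pipeline testable without external
structure downloads:

* :func:`make_toy_complex` emits PDB-format text for an idealized complex —
  a B-form DNA duplex (3.4 Å rise, 36° twist, minimal P/C1'/N1-or-N3 atom
  set) with an optional unpaired tail, and a protein backbone (N, CA, C, O)
  built from ideal internal coordinates (α-helix over an annotated span,
  extended elsewhere), rigidly placed at a controlled minimum protein-DNA
  contact distance.  A ground-truth record accompanies every structure.

* :func:`make_synthetic_table` draws i.i.d. standard-normal features with a
  planted sparse linear signal and Gaussian noise, for selection/stacking
  recovery tests.

These toys exercise the geometric rules exactly; they are not physically
realistic (no side chains, no full bases, no solvent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .catalogue import FEATURE_CATALOGUE
from .classify import BINDING_CUTOFF, assign_class
from .structure import (
    AMINO3_TO_1,
    Atom,
    Chain,
    ComplexStructure,
    Residue,
    ResidueKind,
    SegmentAnnotation,
    SegmentKind,
    to_pdb_string,
)

AMINO1_TO_3 = {v: k for k, v in AMINO3_TO_1.items()}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Ideal backbone internal coordinates (Engh-Huber-like averages).
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
OMEGA = 180.0

HELIX_PHI, HELIX_PSI = -57.0, -47.0
EXTENDED_PHI, EXTENDED_PSI = -139.0, 135.0

# Idealized duplex geometry: WC-edge nitrogens 1.45 Å from the pair midpoint
# (N1-N3 = 2.9 Å), C1' at 5.2 Å (C1'-C1' = 10.4 Å), rise/twist of B-DNA.
DUPLEX_RISE = 3.4
DUPLEX_TWIST = 36.0
R_WC_N = 1.45
R_C1 = 5.2
R_P = 7.0


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Place atom d from three predecessors by bond/angle/dihedral (NeRF)."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(dihedral),
            bond * np.sin(angle) * np.sin(dihedral),
        ]
    )
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local


def build_backbone(phi_psi: list[tuple[float, float]]) -> list[dict[str, np.ndarray]]:
    """Backbone coordinates (N, CA, C, O per residue) from (φ, ψ) lists.

    φ of the first residue is unused; ψ of the last defaults into the O
    placement only.
    """
    n_res = len(phi_psi)
    if n_res < 1:
        raise ValueError("need at least one residue")
    residues: list[dict[str, np.ndarray]] = []
    n0 = np.zeros(3)
    ca0 = n0 + np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(180.0 - ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        psi_prev = phi_psi[i - 1][1]
        n_i = place_atom(
            prev["N"], prev["CA"], prev["C"], BOND_C_N, ANGLE_CA_C_N, psi_prev
        )
        ca_i = place_atom(prev["CA"], prev["C"], n_i, BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        c_i = place_atom(prev["C"], n_i, ca_i, BOND_CA_C, ANGLE_N_CA_C, phi_psi[i][0])
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
    for i, res in enumerate(residues):
        psi = phi_psi[i][1] if i < n_res - 1 else 180.0
        res["O"] = place_atom(
            res["N"], res["CA"], res["C"], BOND_C_O, ANGLE_CA_C_O, psi + 180.0
        )
    return residues


@dataclass(frozen=True)
class ToyComplexSpec:
    n_protein_res: int = 10
    helix_span: tuple[int, int] | None = None  # 1-based residue range
    n_bp: int = 6
    unpaired_tail: int = 0
    min_contact_dist: float = 4.0  # Å
    gc_fraction: float = 0.5
    seed: int = 0
    random_orientation: bool = False

    def __post_init__(self):
        if self.n_protein_res < 1:
            raise ValueError("n_protein_res must be >= 1")
        if self.n_bp < 0 or self.unpaired_tail < 0:
            raise ValueError("counts must be >= 0")
        if self.n_bp + self.unpaired_tail < 1:
            raise ValueError("need at least one nucleotide")
        if self.min_contact_dist <= 0:
            raise ValueError("min_contact_dist must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction in [0, 1]")
        if self.helix_span is not None:
            s, e = self.helix_span
            if not (1 <= s <= e <= self.n_protein_res):
                raise ValueError("helix_span outside the protein")


@dataclass
class ToyGroundTruth:
    protein_seq: str
    helix_span: tuple[int, int] | None
    dna_strand_seqs: list[str]
    n_bp: int
    xix_count: int
    xx_count: int
    paired_fraction: float
    binding_residues: set[tuple[str, int, str]]
    binding_pct: float
    class_label: str
    min_contact_dist: float
    seed: int


def _nucleotide(
    chain_id: str, seq_num: int, base: str,
    c1: np.ndarray, wc_n: np.ndarray, p: np.ndarray,
) -> Residue:
    n_name = "N1" if base in ("A", "G") else "N3"
    return Residue(
        chain_id=chain_id,
        seq_number=seq_num,
        insertion_code="",
        res_name="D" + base,
        atoms=[
            Atom("P", "P", p),
            Atom("C1'", "C", c1),
            Atom(n_name, "N", wc_n),
        ],
        kind=ResidueKind.NUCLEOTIDE,
    )


def _build_dna(
    spec: ToyComplexSpec, rng: np.random.Generator
) -> tuple[list[Chain], list[str], int, int]:
    """Duplex (chains B, C) plus unpaired tail on chain B.

    Returns (chains, strand sequences 5'->3', xix pairs, xx pairs).
    """
    strand1: list[Residue] = []
    strand2: list[Residue] = []
    seq1 = []
    xix = xx = 0
    for i in range(spec.n_bp):
        theta = np.deg2rad(DUPLEX_TWIST * i)
        u = np.array([np.cos(theta), np.sin(theta), 0.0])
        center = np.array([0.0, 0.0, DUPLEX_RISE * i])
        if rng.random() < spec.gc_fraction:
            base1 = rng.choice(["G", "C"])
            xix += 1
        else:
            base1 = rng.choice(["A", "T"])
            xx += 1
        base2 = _COMPLEMENT[base1]
        seq1.append(base1)
        for side, base, store in ((-1.0, base1, strand1), (+1.0, base2, strand2)):
            c1 = center + side * R_C1 * u
            wc_n = center + side * R_WC_N * u
            p = center + side * R_P * u + np.array([0.0, 0.0, 1.0])
            store.append(
                _nucleotide(
                    "B" if side < 0 else "C",
                    len(store) + 1,
                    base,
                    c1,
                    wc_n,
                    p,
                )
            )
    # Antiparallel partner: file order 5'->3' is the reverse of build order.
    strand2 = [
        Residue(r.chain_id, k + 1, "", r.res_name, r.atoms, r.kind)
        for k, r in enumerate(reversed(strand2))
    ]

    tail_seq = []
    z_top = DUPLEX_RISE * max(spec.n_bp - 1, 0)
    for k in range(spec.unpaired_tail):
        base = rng.choice(["A", "C", "G", "T"])
        tail_seq.append(base)
        c1 = np.array([15.0, 0.0, z_top + 6.0 * (k + 1)])
        wc_n = c1 + np.array([3.0, 0.0, 0.0])
        p = c1 + np.array([-2.0, 0.0, 0.0])
        strand1.append(
            _nucleotide("B", len(strand1) + 1, base, c1, wc_n, p)
        )

    seqs = []
    chains = []
    if strand1:
        chains.append(Chain("B", strand1))
        seqs.append("".join(seq1) + "".join(tail_seq))
    if strand2:
        chains.append(Chain("C", strand2))
        seqs.append("".join(_COMPLEMENT[c] for c in reversed(seq1)))
    return chains, seqs, xix, xx


def _build_protein(
    spec: ToyComplexSpec, rng: np.random.Generator
) -> tuple[Chain, str]:
    letters = list(AMINO1_TO_3)
    seq = "".join(rng.choice(letters) for _ in range(spec.n_protein_res))
    phi_psi = []
    for i in range(spec.n_protein_res):
        in_helix = (
            spec.helix_span is not None
            and spec.helix_span[0] <= i + 1 <= spec.helix_span[1]
        )
        phi_psi.append((HELIX_PHI, HELIX_PSI) if in_helix else (EXTENDED_PHI, EXTENDED_PSI))
    backbone = build_backbone(phi_psi)
    residues = []
    for i, (letter, coords) in enumerate(zip(seq, backbone)):
        residues.append(
            Residue(
                chain_id="A",
                seq_number=i + 1,
                insertion_code="",
                res_name=AMINO1_TO_3[letter],
                atoms=[
                    Atom("N", "N", coords["N"]),
                    Atom("CA", "C", coords["CA"]),
                    Atom("C", "C", coords["C"]),
                    Atom("O", "O", coords["O"]),
                ],
                kind=ResidueKind.AMINO_ACID,
            )
        )
    return Chain("A", residues), seq


def _all_coords(chains: list[Chain]) -> np.ndarray:
    return np.vstack([a.coords for ch in chains for r in ch for a in r.atoms])


def _translate(chain: Chain, shift: np.ndarray) -> Chain:
    new_res = []
    for r in chain:
        atoms = [Atom(a.name, a.element, a.coords + shift, a.occupancy) for a in r.atoms]
        new_res.append(
            Residue(r.chain_id, r.seq_number, r.insertion_code, r.res_name, atoms, r.kind)
        )
    return Chain(chain.chain_id, new_res)


def _place_protein(
    protein: Chain, dna_chains: list[Chain], target: float, tol: float = 0.005
) -> Chain:
    """Rigidly translate the protein so min protein-DNA distance == target."""
    dna = _all_coords(dna_chains)
    # Start well clear of the DNA along +x.
    prot = _all_coords([protein])
    shift0 = np.array(
        [dna[:, 0].max() - prot[:, 0].min() + target + 20.0, 0.0, 0.0]
    )
    protein = _translate(protein, shift0)
    for _ in range(80):
        prot = _all_coords([protein])
        d = cdist(prot, dna)
        i, j = np.unravel_index(np.argmin(d), d.shape)
        current = d[i, j]
        if abs(current - target) <= tol:
            return protein
        u = (prot[i] - dna[j]) / current
        protein = _translate(protein, (target - current) * u)
    raise RuntimeError("protein placement did not converge")


def _random_rigid_motion(
    chains: list[Chain], rng: np.random.Generator
) -> list[Chain]:
    # Uniform random rotation from a QR decomposition of a Gaussian matrix.
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-30.0, 30.0, size=3)
    out = []
    for ch in chains:
        new_res = []
        for res in ch:
            atoms = [
                Atom(a.name, a.element, q @ a.coords + t, a.occupancy)
                for a in res.atoms
            ]
            new_res.append(
                Residue(
                    res.chain_id, res.seq_number, res.insertion_code,
                    res.res_name, atoms, res.kind,
                )
            )
        out.append(Chain(ch.chain_id, new_res))
    return out


def make_toy_complex(spec: ToyComplexSpec) -> tuple[str, ToyGroundTruth]:
    """PDB-format text for an idealized complex plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    dna_chains, seqs, xix, xx = _build_dna(spec, rng)
    protein, seq = _build_protein(spec, rng)
    protein = _place_protein(protein, dna_chains, spec.min_contact_dist)
    chains = [protein] + dna_chains
    if spec.random_orientation:
        chains = _random_rigid_motion(chains, rng)
        protein, dna_chains = chains[0], chains[1:]

    # Ground truth binding set by brute-force all-pairs distances.
    dna_coords = _all_coords(dna_chains)
    binding: set[tuple[str, int, str]] = set()
    for res in protein:
        coords = np.vstack([a.coords for a in res.atoms])
        if cdist(coords, dna_coords).min() <= BINDING_CUTOFF:
            binding.add(res.id)
    binding_pct = 100.0 * len(binding) / spec.n_protein_res
    total_nt = 2 * spec.n_bp + spec.unpaired_tail
    paired_fraction = 2.0 * spec.n_bp / total_nt
    label = assign_class(paired_fraction, binding_pct).label

    helix_segments = []
    if spec.helix_span is not None:
        helix_segments.append(
            SegmentAnnotation(SegmentKind.HELIX, "A", spec.helix_span[0], spec.helix_span[1])
        )
    cs = ComplexStructure(
        complex_id=f"toy-{spec.seed}",
        protein_chains=[protein],
        dna_chains=dna_chains,
        helix_segments=helix_segments,
    )
    truth = ToyGroundTruth(
        protein_seq=seq,
        helix_span=spec.helix_span,
        dna_strand_seqs=seqs,
        n_bp=spec.n_bp,
        xix_count=xix,
        xx_count=xx,
        paired_fraction=paired_fraction,
        binding_residues=binding,
        binding_pct=binding_pct,
        class_label=label,
        min_contact_dist=spec.min_contact_dist,
        seed=spec.seed,
    )
    return to_pdb_string(cs), truth


@dataclass(frozen=True)
class SyntheticTableSpec:
    n_rows: int = 60
    n_features: int = 12
    informative_weights: tuple[float, ...] = (2.0, 1.0)  # on the first k columns
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_features < len(self.informative_weights):
            raise ValueError("n_features < number of informative weights")
        if self.n_rows < 1 or self.noise_sd < 0:
            raise ValueError("invalid table spec")


@dataclass
class TableGroundTruth:
    informative: dict[str, float]
    noise_sd: float
    seed: int


def make_synthetic_table(
    spec: SyntheticTableSpec,
) -> tuple[pd.DataFrame, np.ndarray, TableGroundTruth]:
    """Feature table with a planted sparse linear signal.

    Features are i.i.d. standard normal, named after the first
    ``n_features`` catalogue entries; y = Σ wᵢ·xᵢ + N(0, noise_sd).
    """
    rng = np.random.default_rng(spec.seed)
    names = FEATURE_CATALOGUE[: spec.n_features]
    X = rng.standard_normal((spec.n_rows, spec.n_features))
    w = np.zeros(spec.n_features)
    w[: len(spec.informative_weights)] = spec.informative_weights
    y = X @ w + rng.normal(0.0, spec.noise_sd, size=spec.n_rows)
    table = pd.DataFrame(
        X, columns=names, index=[f"cx{i:03d}" for i in range(spec.n_rows)]
    )
    table.index.name = "complex_id"
    truth = TableGroundTruth(
        informative={
            names[i]: float(spec.informative_weights[i])
            for i in range(len(spec.informative_weights))
        },
        noise_sd=spec.noise_sd,
        seed=spec.seed,
    )
    return table, y, truth
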