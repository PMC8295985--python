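"""Residual dipolar couplings: measurement arithmetic, SVD tensor fit, scoring.

An RDC of a fixed bond vector v reports its orientation relative to the
molecular alignment tensor: D(v) = v^T S v, with S the traceless symmetric
Saupe order matrix (the dipolar prefactor is absorbed into S so couplings and
tensor elements are both in Hz). Given five or more non-degenerate bond
vectors the tensor follows linearly from the couplings by singular value
decomposition of the orientation design matrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "RDCSet",
    "BondVectorSet",
    "AlignmentTensor",
    "rdc_from_couplings",
    "extract_nh_vectors",
    "predict_rdc",
    "svd_fit",
    "r_factor",
]


@dataclass
class RDCSet:
    """Observed couplings (Hz) keyed by residue id."""

    d_obs: dict  # residue_id -> Hz
    d_err: dict = None

    def __post_init__(self):
        if self.d_err is None:
            self.d_err = {}
        if not all(math.isfinite(v) for v in self.d_obs.values()):
            raise ValueError("couplings must be finite")


@dataclass
class BondVectorSet:
    """Unit N->H bond vectors in the structure frame, keyed by residue id."""

    vectors: dict  # residue_id -> (3,) unit vector

    def __post_init__(self):
        clean = {}
        for res, v in self.vectors.items():
            v = np.asarray(v, dtype=float)
            if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                raise ValueError(f"bond vector for {res} is not unit length")
            clean[res] = v
        self.vectors = clean


@dataclass
class AlignmentTensor:
    """Saupe order tensor in Hz (dipolar prefactor absorbed).

    ``saupe`` holds the five independent elements (Szz, Syy-Sxx, Sxy, Sxz,
    Syz); the full traceless symmetric 3x3 matrix, the axial magnitude Da,
    the rhombicity R and the z-y-z Euler angles of the principal frame are
    derived from it. Dividing S by the static NH dipolar interaction constant
    recovers the dimensionless order matrix.
    """

    saupe: np.ndarray  # (Szz, Syy-Sxx, Sxy, Sxz, Syz)

    def __post_init__(self):
        self.saupe = np.asarray(self.saupe, dtype=float)
        if self.saupe.shape != (5,):
            raise ValueError("saupe must have 5 elements")

    @classmethod
    def from_matrix(cls, s: np.ndarray) -> "AlignmentTensor":
        s = np.asarray(s, dtype=float)
        if abs(np.trace(s)) > 1e-6 * max(1.0, np.abs(s).max()):
            raise ValueError("Saupe matrix must be traceless")
        return cls(np.array([s[2, 2], s[1, 1] - s[0, 0], s[0, 1], s[0, 2], s[1, 2]]))

    @classmethod
    def axially_symmetric(cls, da_hz: float, rhombicity: float = 0.0) -> "AlignmentTensor":
        """Tensor with principal z-axis along lab z, D(theta) = Da*(3cos^2(theta)-1) + 1.5*Da*R*sin^2(theta)cos(2phi)."""
        szz = 2.0 * da_hz
        sxx = -da_hz * (1.0 - 1.5 * rhombicity)
        syy = -da_hz * (1.0 + 1.5 * rhombicity)
        return cls.from_matrix(np.diag([sxx, syy, szz]))

    @property
    def matrix(self) -> np.ndarray:
        szz, dyx, sxy, sxz, syz = self.saupe
        sxx = -(szz + dyx) / 2.0
        syy = -(szz - dyx) / 2.0
        return np.array([[sxx, sxy, sxz], [sxy, syy, syz], [sxz, syz, szz]])

    def _principal(self):
        evals, evecs = np.linalg.eigh(self.matrix)
        order = np.argsort(np.abs(evals))  # |Sxx'| <= |Syy'| <= |Szz'|
        return evals[order], evecs[:, order]

    @property
    def da_hz(self) -> float:
        """Axial magnitude Da = Szz'/2 in the principal frame (Hz)."""
        evals, _ = self._principal()
        return float(evals[2] / 2.0)

    @property
    def rhombicity(self) -> float:
        """R = (2/3)*(Sxx' - Syy')/Szz'; |R| <= 2/3."""
        evals, _ = self._principal()
        return float((evals[0] - evals[1]) / evals[2] * (2.0 / 3.0))

    @property
    def euler_zyz_deg(self) -> tuple:
        """z-y-z Euler angles (deg) rotating the structure frame onto the principal frame."""
        _, evecs = self._principal()
        rot = evecs
        if np.linalg.det(rot) < 0:
            rot = rot * np.array([1.0, 1.0, -1.0])
        beta = math.acos(np.clip(rot[2, 2], -1.0, 1.0))
        if abs(math.sin(beta)) > 1e-10:
            alpha = math.atan2(rot[1, 2], rot[0, 2])
            gamma = math.atan2(rot[2, 1], -rot[2, 0])
        else:
            alpha = math.atan2(rot[1, 0], rot[0, 0])
            gamma = 0.0
        return tuple(math.degrees(a) for a in (alpha, beta, gamma))

    def to_dict(self) -> dict:
        return {
            "saupe_hz": self.saupe.tolist(),
            "da_hz": self.da_hz,
            "rhombicity": self.rhombicity,
            "euler_zyz_deg": list(self.euler_zyz_deg),
        }


def rdc_from_couplings(j_aligned: float, j_iso: float) -> float:
    """RDC as the difference of J splittings in aligned and isotropic media."""
    return j_aligned - j_iso


def extract_nh_vectors(pdb_path, model_index: int = 0, chain: str | None = None) -> BondVectorSet:
    """Normalized backbone N->H unit vectors from a PDB file.

    Residues lacking an amide proton (prolines, N-terminus without H) are
    skipped with a notice. ``model_index`` selects the model of an NMR
    ensemble (first by default); ``chain`` restricts extraction to one chain.
    """
    import gemmi

    structure = gemmi.read_structure(str(pdb_path))
    if len(structure) == 0:
        raise ValueError(f"no models in {pdb_path}")
    if model_index >= len(structure):
        raise ValueError(f"model {model_index} not present ({len(structure)} models)")
    model = structure[model_index]
    vectors = {}
    for ch in model:
        if chain is not None and ch.name != chain:
            continue
        for residue in ch:
            n_atom = residue.find_atom("N", "*")
            h_atom = residue.find_atom("H", "*") or residue.find_atom("HN", "*")
            if n_atom is None or h_atom is None:
                if n_atom is not None:
                    logger.info(
                        "residue %s %s has no amide H; skipped", residue.name, residue.seqid.num
                    )
                continue
            v = np.array(
                [
                    h_atom.pos.x - n_atom.pos.x,
                    h_atom.pos.y - n_atom.pos.y,
                    h_atom.pos.z - n_atom.pos.z,
                ]
            )
            norm = np.linalg.norm(v)
            if norm == 0:
                logger.warning("zero-length N-H vector at residue %s; skipped", residue.seqid.num)
                continue
            vectors[f"{ch.name}:{residue.seqid.num}"] = v / norm
    if chain is not None and not vectors:
        raise ValueError(f"chain {chain!r} yielded no N-H vectors")
    return BondVectorSet(vectors)


def _design_row(v: np.ndarray) -> np.ndarray:
    # For unit vectors, D = Szz*(3z^2-1)/2 + (Syy-Sxx)*(y^2-x^2)/2
    #                     + 2*Sxy*xy + 2*Sxz*xz + 2*Syz*yz,
    # so the row multiplies the stored (Szz, Syy-Sxx, Sxy, Sxz, Syz) basis directly.
    x, y, z = v
    return np.array(
        [(3.0 * z * z - 1.0) / 2.0, (y * y - x * x) / 2.0, 2.0 * x * y, 2.0 * x * z, 2.0 * y * z]
    )


def predict_rdc(tensor: AlignmentTensor, vectors: BondVectorSet) -> dict:
    """Back-calculated couplings D = v^T S v for every bond vector."""
    s = tensor.matrix
    return {res: float(v @ s @ v) for res, v in vectors.vectors.items()}


class SVDFit(NamedTuple):
    tensor: AlignmentTensor
    d_calc: dict
    r_factor: float
    residues_used: list
    unmatched: list


def svd_fit(rdc: RDCSet, vectors: BondVectorSet) -> SVDFit:
    """Least-squares alignment tensor from couplings and bond orientations.

    Builds the 5-column orientation design matrix over residues present in
    both inputs and solves it by SVD (numpy lstsq). Requires >= 5 matched
    residues with non-degenerate orientations; back-calculated couplings are
    returned for every residue with a vector, and unmatched entries of either
    input are reported.
    """
    matched = [r for r in rdc.d_obs if r in vectors.vectors]
    unmatched = sorted(
        (set(rdc.d_obs) | set(vectors.vectors)) - set(matched), key=str
    )
    if unmatched:
        logger.info("%d entries unmatched between RDCs and vectors: %s", len(unmatched), unmatched)
    if len(matched) < 5:
        raise ValueError(f"need >= 5 matched residues, got {len(matched)}")
    design = np.array([_design_row(vectors.vectors[r]) for r in matched])
    if np.linalg.matrix_rank(design, tol=1e-8) < 5:
        raise ValueError("rank-deficient orientation design: geometry unfittable")
    d = np.array([rdc.d_obs[r] for r in matched])
    sol, *_ = np.linalg.lstsq(design, d, rcond=None)
    tensor = AlignmentTensor(sol)
    d_calc = predict_rdc(tensor, vectors)
    rf = r_factor(d, np.array([d_calc[r] for r in matched]))
    return SVDFit(tensor=tensor, d_calc=d_calc, r_factor=rf, residues_used=matched, unmatched=unmatched)


def r_factor(d_obs: Sequence[float], d_calc: Sequence[float]) -> float:
    """Quality factor R = sqrt(mean((Dobs-Dcalc)^2) / (2*mean(Dobs^2))).

    Zero for perfect agreement; 1/sqrt(2) for an uninformative (all-zero)
    prediction; scale invariant.
    """
    d_obs = np.asarray(d_obs, dtype=float)
    d_calc = np.asarray(d_calc, dtype=float)
    if d_obs.size == 0 or d_obs.shape != d_calc.shape:
        raise ValueError("d_obs and d_calc must be equal-length and non-empty")
    denom = 2.0 * np.mean(d_obs**2)
    if denom == 0:
        raise ValueError("all-zero observed couplings")
    return float(np.sqrt(np.mean((d_obs - d_calc) ** 2) / denom))
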