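"""Substitution scoring for combined 3Di + amino-acid alignment.

Both alphabets use the same 20 uppercase letters (Foldseek convention), plus
``X`` for unknown residues. A single integer "combined" matrix, built as the
rounded weighted sum ``round(w3di * S3di + waa * Saa)``, drives the pairwise
dynamic programming; ``X`` scores 0 against everything.

E-values follow the Karlin-Altschul form ``E = m * n_db * 2**(-bit)`` with
``bit = (lambda * raw - ln K) / ln 2``. Because the combined matrix has no
published parameterization, ``lambda`` and ``K`` are estimated once per model
by fitting a Gumbel distribution to optimal local alignment scores of random
sequence pairs drawn from a uniform background, and cached.
"""

from __future__ import annotations

import importlib.resources
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import gumbel_r

logger = logging.getLogger(__name__)

#: The 20 canonical residue letters, used for both amino acids and 3Di states.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Full alphabet including the wildcard; index 20 is 'X'.
ALPHABET_X = ALPHABET + "X"
X_INDEX = 20

_CHAR_TO_INDEX = {c: i for i, c in enumerate(ALPHABET_X)}
_ENCODE_LUT = np.full(128, X_INDEX, dtype=np.int8)
for _c, _i in _CHAR_TO_INDEX.items():
    _ENCODE_LUT[ord(_c)] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a sequence into int8 indices over :data:`ALPHABET_X`.

    Characters outside the alphabet map to the 'X' index.
    """
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_LUT[raw]


def decode(idx: np.ndarray) -> str:
    return "".join(ALPHABET_X[i] for i in idx)


def read_ncbi_matrix(path: str | Path) -> np.ndarray:
    """Read an NCBI-format substitution matrix into a 21x21 int array.

    Rows/columns are reordered into :data:`ALPHABET_X` order. Letters in the
    file outside the alphabet (e.g. B, Z, *) are ignored; letters of the
    alphabet missing from the file raise. The X row/column is forced to 0
    (the wildcard scores 0 against everything).
    """
    path = Path(path)
    header: list[str] | None = None
    rows: dict[str, list[int]] = {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if header is None:
            header = [p.upper() for p in parts]
            continue
        rows[parts[0].upper()] = [int(round(float(v))) for v in parts[1:]]
    if header is None:
        raise ValueError(f"no matrix header found in {path}")
    mat = np.zeros((21, 21), dtype=np.int32)
    for a in ALPHABET:
        if a not in rows:
            raise ValueError(f"matrix {path} lacks letter {a!r}")
        for b, val in zip(header, rows[a]):
            if b in _CHAR_TO_INDEX and b != "X":
                mat[_CHAR_TO_INDEX[a], _CHAR_TO_INDEX[b]] = val
    mat[X_INDEX, :] = 0
    mat[:, X_INDEX] = 0
    return mat


def write_ncbi_matrix(mat: np.ndarray, path: str | Path) -> None:
    """Write a 21x21 matrix in NCBI text format (letters in alphabet order)."""
    letters = list(ALPHABET_X)
    lines = ["   " + "  ".join(letters)]
    for i, a in enumerate(letters):
        lines.append(a + " " + " ".join(f"{int(mat[i, j]):3d}" for j in range(21)))
    Path(path).write_text("\n".join(lines) + "\n")


def default_3di_matrix() -> np.ndarray:
    """Default structural-alphabet matrix shipped with the package.

    A synthetic uniform matrix (match +6, mismatch -3, X = 0) matched to a
    uniform substitution process over the 20 3Di states; replaceable by any
    NCBI-format file via :func:`read_ncbi_matrix`.
    """
    ref = importlib.resources.files("structcore.data") / "mat3di.synthetic.txt"
    with importlib.resources.as_file(ref) as p:
        return read_ncbi_matrix(p)


def default_aa_matrix() -> np.ndarray:
    """BLOSUM62 from biopython, with X forced to score 0."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((21, 21), dtype=np.int32)
    for a in ALPHABET:
        for b in ALPHABET:
            mat[_CHAR_TO_INDEX[a], _CHAR_TO_INDEX[b]] = int(blosum[a, b])
    return mat


_CALIBRATION_CACHE: dict[bytes, tuple[float, float]] = {}


@dataclass
class SubstitutionModel:
    """Scoring model for combined 3Di + AA local alignment.

    Parameters
    ----------
    mat3di, mataa : (21, 21) integer matrices over ``ALPHABET_X``.
    w3di, waa : nonnegative channel weights (Foldseek's 2.1 / 1.4 convention).
    gap_open, gap_extend : positive affine gap penalties on the combined scale.
    lambda_, k_const : Karlin-Altschul parameters; estimated lazily when None.
    """

    mat3di: np.ndarray = field(default_factory=default_3di_matrix)
    mataa: np.ndarray = field(default_factory=default_aa_matrix)
    w3di: float = 2.1
    waa: float = 1.4
    gap_open: int = 10
    gap_extend: int = 1
    lambda_: float | None = None
    k_const: float | None = None

    def __post_init__(self) -> None:
        self.mat3di = np.asarray(self.mat3di, dtype=np.int32)
        self.mataa = np.asarray(self.mataa, dtype=np.int32)
        for name, m in (("mat3di", self.mat3di), ("mataa", self.mataa)):
            if m.shape != (21, 21):
                raise ValueError(f"{name} must be 21x21 (20 letters + X)")
            if not np.array_equal(m, m.T):
                raise ValueError(f"{name} must be symmetric")
        if self.w3di < 0 or self.waa < 0 or self.w3di + self.waa == 0:
            raise ValueError("weights must be nonnegative, not both zero")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        exp = (
            self.w3di * self.mat3di[:20, :20].mean()
            + self.waa * self.mataa[:20, :20].mean()
        )
        if exp >= 0:
            logger.warning(
                "weighted scoring scheme has nonnegative expected score "
                "(%.3f) under uniform background; E-values will be "
                "unreliable", exp,
            )

    def aa_only(self) -> "SubstitutionModel":
        """The same model with the structural channel switched off."""
        return SubstitutionModel(
            mat3di=self.mat3di, mataa=self.mataa, w3di=0.0, waa=self.waa,
            gap_open=self.gap_open, gap_extend=self.gap_extend,
        )

    # -- Karlin-Altschul calibration -------------------------------------

    def ensure_calibrated(self, n_pairs: int = 300, length: int = 150) -> None:
        """Estimate lambda and K from random-pair local alignment scores.

        Scores of optimal gapped local alignments of i.i.d. uniform sequences
        follow an extreme-value (Gumbel) law; we fit location/scale with scipy
        and convert: ``lambda = 1/scale``, ``K = exp(lambda*loc) / (m*n)``.
        Deterministic (fixed internal seed) and cached per scoring scheme.
        """
        if self.lambda_ is not None and self.k_const is not None:
            return
        key = (
            self.mat3di.tobytes() + self.mataa.tobytes()
            + np.float64([self.w3di, self.waa]).tobytes()
            + np.int64([self.gap_open, self.gap_extend]).tobytes()
        )
        if key in _CALIBRATION_CACHE:
            self.lambda_, self.k_const = _CALIBRATION_CACHE[key]
            return
        from ._kernels import local_align_stats

        rng = np.random.default_rng(20240901)
        scores = np.empty(n_pairs)
        for i in range(n_pairs):
            t_a = rng.integers(0, 20, size=length)
            t_b = rng.integers(0, 20, size=length)
            a_a = rng.integers(0, 20, size=length)
            a_b = rng.integers(0, 20, size=length)
            s = self.score_pair_matrix(t_a, t_b, a_a, a_b)
            scores[i] = local_align_stats(s, self.gap_open, self.gap_extend)[0]
        loc, scale = gumbel_r.fit(scores)
        lam = 1.0 / scale
        k = math.exp(lam * loc) / (length * length)
        _CALIBRATION_CACHE[key] = (lam, k)
        self.lambda_, self.k_const = lam, k
        logger.info("calibrated lambda=%.4f K=%.3g", lam, k)

    def bit_score(self, raw: float) -> float:
        self.ensure_calibrated()
        return (self.lambda_ * raw - math.log(self.k_const)) / math.log(2.0)

    def evalue(self, raw: float, m: int, n_db: int) -> float:
        """Expected chance hits at this score: ``m * n_db * 2**(-bit)``."""
        return float(m) * float(n_db) * 2.0 ** (-self.bit_score(raw))

    def score_pair_matrix(self, tdi_a, tdi_b, aa_a, aa_b) -> np.ndarray:
        """Position-pair combined score matrix for two encoded records.

        ``S[i, j] = round(w3di*S3di(t_i, t_j) + waa*Saa(a_i, a_j))`` — the
        weighted channel sum rounded once, keeping raw scores integral.
        """
        tdi_a = np.asarray(tdi_a, dtype=np.intp)
        tdi_b = np.asarray(tdi_b, dtype=np.intp)
        aa_a = np.asarray(aa_a, dtype=np.intp)
        aa_b = np.asarray(aa_b, dtype=np.intp)
        s = self.w3di * self.mat3di[tdi_a[:, None], tdi_b[None, :]] \
            + self.waa * self.mataa[aa_a[:, None], aa_b[None, :]]
        return np.rint(s).astype(np.int32)
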