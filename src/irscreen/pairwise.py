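"""Global pairwise protein alignment and percent-identity matrices.

The divergence screen compares full-length orthologs, so alignment is global
(Needleman-Wunsch with affine gaps) rather than local. Scoring defaults to
BLOSUM62 with gap open 11 / extend 1, the protein-BLAST defaults; a gap of
length k costs open + k*extend. The engine is Bio.Align.PairwiseAligner,
whose first traceback is deterministic.

Percent identity is identical columns / total alignment columns x 100 (the
BLAST reporting convention); ``denominator="shorter"`` divides by the shorter
ungapped sequence length instead. The ambiguity letter X scores zero against
everything and never counts as an identity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import MissingOrthologError
from .seqio import OrthologGroup

DEFAULT_MATRIX = "BLOSUM62"
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

DENOMINATORS = ("alignment", "shorter")


@dataclass(frozen=True)
class AlignmentResult:
    """A global alignment of two sequences with its identity bookkeeping."""

    aligned_a: str
    aligned_b: str
    score: float
    identities: int
    alignment_length: int


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric percent-identity matrix over an ordered species panel."""

    species: tuple[str, ...]
    pid: np.ndarray  # percent, [0, 100]

    def __post_init__(self) -> None:
        n = len(self.species)
        if self.pid.shape != (n, n):
            raise ValueError("pid matrix shape does not match species panel")
        if not np.allclose(self.pid, self.pid.T):
            raise ValueError("pid matrix is not symmetric")
        if not np.all(np.isfinite(self.pid)):
            raise ValueError("pid matrix contains non-finite values")

    def get(self, a: str, b: str) -> float:
        return float(self.pid[self.species.index(a), self.species.index(b)])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.pid, index=self.species, columns=self.species)


@lru_cache(maxsize=None)
def _load_matrix(name: str):
    mat = substitution_matrices.load(name)
    if "X" in mat.alphabet:
        # X is fully ambiguous: no information, no reward, no penalty.
        xi = mat.alphabet.index("X")
        mat[xi, :] = 0.0
        mat[:, xi] = 0.0
    return mat


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    aligner = Align.PairwiseAligner(mode="global")
    aligner.substitution_matrix = _load_matrix(matrix)
    # PairwiseAligner charges open_gap_score for the first gap column and
    # extend_gap_score for each further column; open + k*extend overall.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _count_identities(aligned_a: str, aligned_b: str) -> int:
    return sum(
        ca == cb and ca != "-" and ca != "X"
        for ca, cb in zip(aligned_a, aligned_b)
    )


def global_align(
    a: str,
    b: str,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> AlignmentResult:
    """Optimal global affine-gap alignment of two protein sequences."""
    if not a or not b:
        # The engine rejects empty inputs; the optimal alignment is all-gap.
        gapped = a or b
        cost = -(gap_open + gap_extend * len(gapped)) if gapped else 0.0
        return AlignmentResult(
            aligned_a=a or "-" * len(gapped),
            aligned_b=b or "-" * len(gapped),
            score=cost,
            identities=0,
            alignment_length=len(gapped),
        )
    sub = _load_matrix(matrix)
    for residue in itertools.chain(a, b):
        if residue not in sub.alphabet:
            raise ValueError(
                f"residue {residue!r} has no entry in scoring matrix {matrix}"
            )
    aln = _aligner(matrix, gap_open, gap_extend).align(a, b)[0]
    aligned_a, aligned_b = aln[0], aln[1]
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        identities=_count_identities(aligned_a, aligned_b),
        alignment_length=len(aligned_a),
    )


def percent_identity(result: AlignmentResult, denominator: str = "alignment") -> float:
    """Percent identity of an alignment; see module docstring for conventions."""
    if denominator not in DENOMINATORS:
        raise ValueError(f"denominator must be one of {DENOMINATORS}")
    if result.alignment_length == 0:
        raise ValueError("percent identity undefined for a zero-length alignment")
    if denominator == "alignment":
        denom = result.alignment_length
    else:
        denom = min(
            len(result.aligned_a.replace("-", "")),
            len(result.aligned_b.replace("-", "")),
        )
        if denom == 0:
            raise ValueError("percent identity undefined: an input is empty")
    return 100.0 * result.identities / denom


def identity_matrix(
    group: OrthologGroup,
    panel,
    matrix: str = DEFAULT_MATRIX,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    denominator: str = "alignment",
) -> IdentityMatrix:
    """Align every unordered species pair once and collect percent identities."""
    panel = tuple(panel)
    missing = [sp for sp in panel if sp not in group.members]
    if missing:
        raise MissingOrthologError(group.gene_symbol, missing)
    n = len(panel)
    pid = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            res = global_align(
                group.members[panel[i]].sequence,
                group.members[panel[j]].sequence,
                matrix=matrix,
                gap_open=gap_open,
                gap_extend=gap_extend,
            )
            pid[i, j] = pid[j, i] = percent_identity(res, denominator=denominator)
    return IdentityMatrix(panel, pid)


def write_identity_matrix(m: IdentityMatrix, path) -> None:
    """Square TSV with a species header row and column, 2-decimal percents."""
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(m.species) + "\n")
        for i, sp in enumerate(m.species):
            fh.write(sp + "\t" + "\t".join(f"{v:.2f}" for v in m.pid[i]) + "\n")


def write_alignment_fasta(result: AlignmentResult, path, names=("a", "b")) -> None:
    """Emit one pairwise alignment as aligned FASTA (gap character '-')."""
    with open(path, "w") as fh:
        for name, seq in zip(names, (result.aligned_a, result.aligned_b)):
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")
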