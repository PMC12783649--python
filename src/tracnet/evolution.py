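"""Evolutionary conservation and specificity of alignment positions.

Conservation is scored per alignment column with a Von Neumann entropy
that is aware of amino-acid chemical similarity: from the column's residue
frequencies P (diagonal) and a unit-diagonal similarity matrix S derived
from BLOSUM50, the density matrix

    rho = P^{1/2} S P^{1/2} / tr(P^{1/2} S P^{1/2})

is symmetric positive semidefinite with trace 1, and

    S_i = - sum_k  lambda_k log_20 lambda_k,    C_i = 1 - S_i

with lambda_k the eigenvalues of rho.  The base-20 logarithm makes the
maximum possible entropy exactly 1 (a uniform column under identity
similarity), so C_i runs from 0 (maximally diverse) to 1 (invariant).

For subtype specificity, positions within a residue subset are classified
as "fully conserved" (one residue type across all classes) or "perfectly
specific" to a class (invariant within the class and that residue absent
from every other class); the specificity ratio rho = log2(|S| / |C|)
summarizes which evolutionary force dominates the subset (negative:
purifying / conservation; positive: adaptive / specificity).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "LabeledMSA",
    "ConservationProfile",
    "SpecificityResult",
    "blosum50_similarity",
    "column_density_matrix",
    "vn_entropy",
    "conservation_score",
    "classify_positions",
    "specificity_ratio",
    "read_labeled_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
LOW_CONFIDENCE_GAP_FRACTION = 0.5


@dataclass
class LabeledMSA:
    """Aligned sequences with one class label per sequence."""

    sequences: list[str]
    labels: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty alignment")
        L = len(self.sequences[0])
        if any(len(s) != L for s in self.sequences):
            raise ValueError("all sequences must have equal aligned length")
        if len(self.labels) != len(self.sequences):
            raise ValueError("one class label per sequence required")
        bad = set("".join(self.sequences).upper()) - set(AMINO_ACIDS + GAP)
        if bad:
            raise ValueError(f"non-standard alignment characters: {sorted(bad)}")
        self.sequences = [s.upper() for s in self.sequences]
        if not self.ids:
            self.ids = [f"seq{i}" for i in range(len(self.sequences))]

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def column(self, i: int) -> list[str]:
        """Residues of 1-based column ``i``."""
        return [s[i - 1] for s in self.sequences]


@dataclass
class ConservationProfile:
    """Per-column entropies and conservation scores (NaN for all-gap columns)."""

    entropy: np.ndarray  # S_i in [0, 1]
    score: np.ndarray  # C_i = 1 - S_i
    eigenvalues: list[np.ndarray | None]
    gap_fraction: np.ndarray
    annotations: dict[str, list[int]] = field(default_factory=dict)

    @property
    def low_confidence(self) -> np.ndarray:
        return self.gap_fraction > LOW_CONFIDENCE_GAP_FRACTION

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "position": np.arange(1, self.entropy.size + 1),
                "entropy": self.entropy,
                "score": self.score,
                "gap_fraction": self.gap_fraction,
            }
        )
        for name, positions in self.annotations.items():
            df[name] = df["position"].isin(positions)
        return df


@dataclass
class SpecificityResult:
    """Fully conserved vs perfectly specific positions over a position subset."""

    target_class: str
    conserved: list[int]  # 1-based positions
    specific: list[int]
    positions: list[int]

    @property
    def ratio(self) -> float:
        return specificity_ratio(len(self.specific), len(self.conserved))


def blosum50_similarity() -> np.ndarray:
    """Unit-diagonal similarity in [0, 1] derived from BLOSUM50.

    Raw BLOSUM entries are log-odds scores with negative values; they are
    min-max mapped to [0, 1] and rescaled so diagonal entries are exactly 1:
    s_ab = b'_ab / sqrt(b'_aa b'_bb), clipped to [0, 1].
    """
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM50")
    b = np.array(
        [[blosum[a, c] for c in AMINO_ACIDS] for a in AMINO_ACIDS], dtype=float
    )
    b = (b - b.min()) / (b.max() - b.min())
    d = np.sqrt(np.diag(b))
    s = b / np.outer(d, d)
    return np.clip(s, 0.0, 1.0)


def column_density_matrix(
    column: list[str] | str,
    similarity: np.ndarray | None = None,
    form: str = "symmetric",
) -> np.ndarray | None:
    """Density matrix of one alignment column.

    Gaps are dropped and frequencies renormalized; an all-gap column yields
    ``None`` (missing).  With ``similarity=None`` the BLOSUM50-derived
    matrix is used; pass ``np.eye(20)`` for the similarity-blind variant.

    ``form="symmetric"`` (default) builds P^{1/2} S P^{1/2}, which is
    symmetric PSD and therefore has a real non-negative spectrum;
    ``form="product"`` builds the trace-normalized P S for comparison
    (its spectrum is not guaranteed real, so :func:`vn_entropy` only
    accepts the symmetric form).
    """
    if similarity is None:
        similarity = blosum50_similarity()
    similarity = np.asarray(similarity, dtype=float)
    if similarity.shape != (20, 20):
        raise ValueError("similarity must be 20x20 over the standard amino acids")
    counts = np.zeros(20)
    for aa in column:
        aa = aa.upper()
        if aa == GAP:
            continue
        if aa not in _AA_INDEX:
            raise ValueError(f"unknown residue {aa!r}")
        counts[_AA_INDEX[aa]] += 1
    if counts.sum() == 0:
        return None
    p = counts / counts.sum()
    if form == "symmetric":
        sqrt_p = np.sqrt(p)
        m = sqrt_p[:, None] * similarity * sqrt_p[None, :]
    elif form == "product":
        m = p[:, None] * similarity
    else:
        raise ValueError(f"unknown density form {form!r}")
    return m / np.trace(m)


def vn_entropy(rho: np.ndarray) -> float:
    """Base-20 Von Neumann entropy of a density matrix, in [0, 1]."""
    rho = np.asarray(rho, dtype=float)
    if abs(np.trace(rho) - 1.0) > 1e-8:
        raise ValueError(f"density matrix trace {np.trace(rho)} != 1")
    lam = np.linalg.eigvalsh(rho)
    lam = lam[lam > 1e-12]
    return float(-(lam * np.log(lam)).sum() / math.log(20))


def conservation_score(
    msa: LabeledMSA,
    similarity: np.ndarray | None = None,
    annotations: dict[str, list[int]] | None = None,
) -> ConservationProfile:
    """Per-column conservation C_i = 1 - S_i across the alignment.

    ``annotations`` maps a residue-set name (e.g. "central", "connector",
    "neighborhood") to 1-based positions, carried into the profile so score
    distributions can be compared across sets.
    """
    if similarity is None:
        similarity = blosum50_similarity()
    L = msa.n_columns
    n = len(msa.sequences)
    entropy = np.full(L, np.nan)
    eigenvalues: list[np.ndarray | None] = []
    gap_fraction = np.zeros(L)
    for i in range(1, L + 1):
        col = msa.column(i)
        gap_fraction[i - 1] = sum(c == GAP for c in col) / n
        rho = column_density_matrix(col, similarity)
        if rho is None:
            eigenvalues.append(None)
            continue
        lam = np.linalg.eigvalsh(rho)
        eigenvalues.append(lam)
        entropy[i - 1] = vn_entropy(rho)
    score = 1.0 - entropy
    return ConservationProfile(
        entropy, score, eigenvalues, gap_fraction, annotations or {}
    )


def classify_positions(
    msa: LabeledMSA,
    positions: list[int],
    target_class: str,
    gap_disqualifies: bool = True,
) -> SpecificityResult:
    """Partition ``positions`` (1-based) into fully conserved / perfectly
    specific-to-``target_class`` sets.

    Fully conserved: exactly one residue type across all sequences of all
    classes.  Perfectly specific: all target-class sequences share one
    residue type and that type never occurs at the position in any other
    class.  With ``gap_disqualifies`` (default) any gap removes a position
    from the conserved set; gaps in non-target classes never block
    specificity (only residue identity does).
    """
    if not positions:
        raise ValueError("empty position subset")
    if target_class not in msa.labels:
        raise ValueError(f"class {target_class!r} not present in alignment labels")
    L = msa.n_columns
    bad = [p for p in positions if not 1 <= p <= L]
    if bad:
        raise ValueError(f"positions out of alignment range [1, {L}]: {bad}")
    conserved, specific = [], []
    for pos in positions:
        col = msa.column(pos)
        residues = set(col)
        non_gap = residues - {GAP}
        if len(non_gap) == 1 and (GAP not in residues or not gap_disqualifies):
            conserved.append(pos)
            continue
        in_class = {c for c, lab in zip(col, msa.labels) if lab == target_class}
        out_class = {c for c, lab in zip(col, msa.labels) if lab != target_class}
        if len(in_class) == 1 and GAP not in in_class:
            (res,) = in_class
            if res not in out_class:
                specific.append(pos)
    return SpecificityResult(target_class, conserved, specific, list(positions))


def specificity_ratio(n_specific: int, n_conserved: int) -> float:
    """rho = log2(|S| / |C|) with infinity/NaN sentinels for empty sets."""
    if n_specific < 0 or n_conserved < 0:
        raise ValueError("counts must be non-negative")
    if n_specific == 0 and n_conserved == 0:
        return float("nan")
    if n_conserved == 0:
        return float("inf")
    if n_specific == 0:
        return float("-inf")
    return math.log2(n_specific / n_conserved)


def read_labeled_fasta(
    fasta_path, labels: "dict[str, str] | str | None" = None
) -> LabeledMSA:
    """Read an aligned FASTA; class labels from a sidecar mapping, a CSV
    path (columns id,label), or parsed as the suffix after the last '|' of
    each record id."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {fasta_path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    if labels is None:
        if not all("|" in i for i in ids):
            raise ValueError("no label mapping given and ids carry no '|label' suffix")
        labs = [i.rsplit("|", 1)[1] for i in ids]
    elif isinstance(labels, dict):
        labs = [labels[i] for i in ids]
    else:
        table = pd.read_csv(labels)
        mapping = dict(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str)))
        labs = [mapping[i] for i in ids]
    return LabeledMSA(seqs, labs, ids)
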