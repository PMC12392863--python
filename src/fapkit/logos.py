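"""Position-frequency matrices, information content and consensus motifs.

The imperfect repeats of FapB/FapC are ~38-39 residues long and strongly
conserved at specific positions (invariant glycines, an Asn/Gln ladder, and
hydrophobic-core positions).  Given a set of aligned repeat sequences this
module builds a position-frequency matrix (PFM), computes per-column
information content in bits (IC = log2 20 − column entropy), and renders a
consensus-motif string in the conventional notation: capital letters for
complete conservation, lowercase for high conservation, Ψ for hydrophobic
positions, (x/y) for an even split between two residues, and * for
unconserved columns.

Gaps are tracked per column but excluded from the 20-letter frequency
simplex, following sequence-logo convention; alignment itself (HMM
match-state columns) happens upstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "DEFAULT_HYDROPHOBIC",
    "RepeatAlignment",
    "PFM",
    "ConsensusThresholds",
    "ConsensusMotif",
    "build_pfm",
    "column_information",
    "consensus_motif",
    "read_alignment_fasta",
    "write_column_table",
    "render_logo",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Residues counted as hydrophobic for the Ψ motif symbol.  S, T and Y are
#: excluded: the motif notation distinguishes small-polar (a/s) positions
#: from genuinely hydrophobic ones.
DEFAULT_HYDROPHOBIC = frozenset("AVLIMFWC")


@dataclass
class RepeatAlignment:
    """Equal-length aligned sequences over the 20 amino acids plus '-'."""

    sequences: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment needs at least one sequence")
        L = len(self.sequences[0])
        alphabet = set(AMINO_ACIDS + GAP)
        for i, s in enumerate(self.sequences):
            if len(s) != L:
                raise ValueError(
                    f"ragged alignment: sequence {i} has length {len(s)}, expected {L}"
                )
            bad = set(s.upper()) - alphabet
            if bad:
                raise ValueError(f"illegal character(s) {sorted(bad)} in sequence {i}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])


@dataclass
class PFM:
    """Per-column residue frequencies (rows sum to 1 over non-gap symbols)."""

    freqs: np.ndarray  # (n_columns, 20)
    gap_fraction: np.ndarray  # (n_columns,)
    label: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.gap_fraction = np.asarray(self.gap_fraction, dtype=float)
        if self.freqs.ndim != 2 or self.freqs.shape[1] != len(AMINO_ACIDS):
            raise ValueError("freqs must be (n_columns, 20)")
        if self.gap_fraction.shape != (self.freqs.shape[0],):
            raise ValueError("gap_fraction length mismatch")
        sums = self.freqs.sum(axis=1)
        nonempty = sums > 0
        if not np.allclose(sums[nonempty], 1.0, atol=1e-9):
            raise ValueError("non-gap column frequencies must sum to 1")

    @property
    def n_columns(self) -> int:
        return self.freqs.shape[0]


@dataclass(frozen=True)
class ConsensusThresholds:
    """Frequency thresholds behind the motif notation (tunable)."""

    complete: float = 0.97  # capital letter
    high: float = 0.60  # lowercase letter
    hydrophobic: float = 0.60  # summed hydrophobic frequency for Ψ
    pair: float = 0.30  # each of the top two residues for (x/y)
    pair_ratio: float = 2.0  # top two within this factor of each other
    hydrophobic_set: frozenset = DEFAULT_HYDROPHOBIC


@dataclass
class ConsensusMotif:
    motif: str
    tokens: list[str] = field(default_factory=list)
    classes: list[str] = field(default_factory=list)  # per column


def build_pfm(aln: RepeatAlignment, pseudocount: float = 0.0) -> PFM:
    """Count residues per column; gaps are tracked separately.

    ``pseudocount`` optionally adds Laplace smoothing to the residue counts
    (off by default).
    """
    L = aln.n_columns
    counts = np.zeros((L, len(AMINO_ACIDS)))
    gaps = np.zeros(L)
    for s in aln.sequences:
        for j, c in enumerate(s):
            if c == GAP:
                gaps[j] += 1
            else:
                counts[j, _AA_INDEX[c]] += 1
    counts += pseudocount
    totals = counts.sum(axis=1)
    freqs = np.zeros_like(counts)
    nonzero = totals > 0
    freqs[nonzero] = counts[nonzero] / totals[nonzero, None]
    return PFM(freqs=freqs, gap_fraction=gaps / len(aln.sequences), label=aln.label)


def column_information(pfm: PFM, small_sample_n: int | None = None) -> np.ndarray:
    """Information content per column in bits: log2(20) − Shannon entropy.

    Ranges from 0 (uniform column) to log2 20 ≈ 4.32 (point mass).  With
    ``small_sample_n`` the standard small-sample correction
    (20 − 1) / (2 n ln 2) is subtracted and clipped at zero (off by
    default).
    """
    p = pfm.freqs
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = np.log2(len(AMINO_ACIDS)) - entropy
    # all-gap columns carry no residue information
    ic[pfm.freqs.sum(axis=1) == 0] = 0.0
    if small_sample_n is not None:
        ic = np.clip(ic - (len(AMINO_ACIDS) - 1) / (2 * small_sample_n * np.log(2)), 0.0, None)
    return ic


def consensus_motif(
    pfm: PFM, thresholds: ConsensusThresholds = ConsensusThresholds()
) -> ConsensusMotif:
    """Classify each column and emit the consensus-motif string.

    Priority per column: complete conservation (capital) > high conservation
    (lowercase) > hydrophobic Ψ (summed hydrophobic frequency above the
    threshold with no single dominant residue) > even pair "(x/y)" (top two
    residues each frequent and within a factor ``pair_ratio``) > '*'.
    """
    t = thresholds
    hydro_idx = [_AA_INDEX[a] for a in sorted(t.hydrophobic_set)]
    tokens: list[str] = []
    classes: list[str] = []
    for j in range(pfm.n_columns):
        f = pfm.freqs[j]
        if f.sum() == 0:  # all-gap column
            tokens.append("*")
            classes.append("none")
            continue
        order = np.argsort(-f, kind="stable")
        top, second = order[0], order[1]
        if f[top] >= t.complete:
            tokens.append(AMINO_ACIDS[top])
            classes.append("complete")
        elif f[top] >= t.high:
            tokens.append(AMINO_ACIDS[top].lower())
            classes.append("high")
        elif f[hydro_idx].sum() >= t.hydrophobic:
            tokens.append("Ψ")
            classes.append("hydrophobic")
        elif f[second] >= t.pair and f[top] <= t.pair_ratio * f[second]:
            x, y = sorted(AMINO_ACIDS[i].lower() for i in (top, second))
            tokens.append(f"({x}/{y})")
            classes.append("pair")
        else:
            tokens.append("*")
            classes.append("none")
    return ConsensusMotif(motif="".join(tokens), tokens=tokens, classes=classes)


# ---------------------------------------------------------------------------
# I/O and rendering


def read_alignment_fasta(path: str | Path, label: str = "") -> RepeatAlignment:
    from Bio import SeqIO

    seqs = [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    return RepeatAlignment(sequences=seqs, label=label or Path(path).stem)


def write_column_table(pfm: PFM, path: str | Path, thresholds=ConsensusThresholds()) -> None:
    """Per-column TSV: frequencies, gap fraction, bits and consensus class."""
    import pandas as pd

    ic = column_information(pfm)
    motif = consensus_motif(pfm, thresholds)
    df = pd.DataFrame(pfm.freqs, columns=list(AMINO_ACIDS))
    df.insert(0, "column", np.arange(1, pfm.n_columns + 1))
    df["gap_fraction"] = pfm.gap_fraction
    df["bits"] = ic
    df["class"] = motif.classes
    df["token"] = motif.tokens
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def render_logo(pfm: PFM, path: str | Path, dpi: int = 150) -> None:
    """Render a simple sequence logo (letter height = frequency × bits)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ic = column_information(pfm)
    fig, ax = plt.subplots(figsize=(max(4, pfm.n_columns * 0.35), 2.5))
    cmap = {"G": "tab:orange", "P": "tab:orange"}
    hydrophobic = set("AVLIMFWC")
    for j in range(pfm.n_columns):
        order = np.argsort(pfm.freqs[j])
        y = 0.0
        for i in order:
            h = pfm.freqs[j, i] * ic[j]
            if h < 0.01:
                continue
            aa = AMINO_ACIDS[i]
            color = cmap.get(aa, "tab:blue" if aa in hydrophobic else "tab:green")
            ax.text(
                j + 0.5, y + h / 2, aa,
                ha="center", va="center",
                fontsize=6 + 10 * min(h / np.log2(20), 1.0),
                color=color, family="monospace",
            )
            y += h
    ax.set_xlim(0, pfm.n_columns)
    ax.set_ylim(0, np.log2(20))
    ax.set_xlabel("column")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
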