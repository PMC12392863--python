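"""Seeded generators of synthetic inputs for every pipeline stage.

Each generator is a pure function of its configuration and seed and returns
a ground-truth manifest alongside the data, so pipeline output can be
compared against planted truth rather than hard-coded constants.  The
defaults emulate the statistical structure of the real study system: fap
operons are planted as fapABCDEF gene runs with configurable intergenic
gaps (including gaps straddling the 5000 bp clustering threshold), repeat
sequences are drawn from a FapC-motif-like position-frequency matrix,
scattering curves come from the cylinder + chain forward model with
multiplicative Gaussian noise, helical traces are planar pseudo-atom motifs
stacked by screw symmetry, and height profiles are sinusoids (≈1 nm
amplitude, the half-crossover period) with additive noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .afm import HeightProfile
from .helix import AtomicModel, HelicalParams, build_helical_assembly
from .logos import AMINO_ACIDS, DEFAULT_HYDROPHOBIC, PFM
from .operon import GeneRecord
from .saxs import CylinderParams, SAXSCurve, model_intensity

__all__ = [
    "SynthGenomeConfig",
    "SynthGenome",
    "synth_fap_genome",
    "write_domtblout",
    "fapc_like_pfm",
    "FAPC_MOTIF_TOKENS",
    "synth_repeat_set",
    "synth_saxs_curve",
    "synth_helical_trace",
    "synth_height_profile",
]

_FAP_ORDER = ("FapA", "FapBC_repeat", "FapBC_repeat", "FapD", "FapE", "FapF")
_FAP_ROLES = ("fapA", "fapB", "fapC", "fapD", "fapE", "fapF")

#: Typical protein lengths (aa) for the operon genes; fapB/fapC lengths are
#: derived from their repeat layout instead.
_GENE_AA = {"fapA": 152, "fapD": 250, "fapE": 120, "fapF": 430}


@dataclass
class SynthGenomeConfig:
    """Layout of a synthetic genome with planted fap operons.

    ``intergenic_gap_bp`` applies between consecutive operon genes; a
    mapping in ``gap_overrides`` keyed by (operon index, junction index)
    overrides individual gaps, enabling boundary cases at 4999/5000 bp.
    Repeat counts may be a single integer or one value per operon.
    """

    n_operons: int = 10
    intergenic_gap_bp: int = 200
    gap_overrides: dict[tuple[int, int], int] = field(default_factory=dict)
    repeats_fapB: int | Sequence[int] = 3
    repeats_fapC: int | Sequence[int] = 3
    n_decoys: int = 0
    decoy_evalue: float = 1e-2  # above the 1e-5 cutoff: filtered at parse time
    hit_evalue: float = 1e-40
    repeat_len_aa: int = 39
    linker_len_aa: int = 14
    repeat_start_aa: int = 45
    genome_id: str = "synthG1"


@dataclass
class SynthGenome:
    genes: list[GeneRecord]
    domtblout_text: str
    fasta_text: str
    manifest: dict


def _per_operon(value, n: int, name: str) -> list[int]:
    if isinstance(value, (int, np.integer)):
        return [int(value)] * n
    vals = list(value)
    if len(vals) != n:
        raise ValueError(f"{name}: expected {n} values, got {len(vals)}")
    return [int(v) for v in vals]


def _random_protein(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def _repeat_layout(cfg: SynthGenomeConfig, n_repeats: int) -> list[tuple[int, int]]:
    spans = []
    start = cfg.repeat_start_aa
    for _ in range(n_repeats):
        spans.append((start, start + cfg.repeat_len_aa - 1))
        start += cfg.repeat_len_aa + cfg.linker_len_aa
    return spans


def synth_fap_genome(cfg: SynthGenomeConfig, seed: int) -> SynthGenome:
    """Plant fapABCDEF operons and emit the files the mining stage consumes.

    Each operon occupies its own contig; decoy genes (HMM hits with
    e-values above the cutoff) go on a separate contig.  Returns the gene
    records, HMMER3 domtblout text, protein FASTA, and a manifest with the
    planted truth (roles, repeat counts and spans, gap lists).
    """
    if cfg.n_operons < 0 or cfg.n_decoys < 0:
        raise ValueError("n_operons and n_decoys must be nonnegative")
    for key, gap in cfg.gap_overrides.items():
        op, junction = key
        if not (0 <= op < cfg.n_operons and 0 <= junction < len(_FAP_ORDER) - 1):
            raise ValueError(f"gap override {key} outside operon layout")
        if gap < 0:
            raise ValueError("gaps must be nonnegative")
    rng = np.random.default_rng(seed)
    reps_B = _per_operon(cfg.repeats_fapB, cfg.n_operons, "repeats_fapB")
    reps_C = _per_operon(cfg.repeats_fapC, cfg.n_operons, "repeats_fapC")
    pfm = fapc_like_pfm()

    genes: list[GeneRecord] = []
    fasta_chunks: list[str] = []
    dom_rows: list[dict] = []
    manifest: dict = {"genome_id": cfg.genome_id, "operons": [], "decoys": []}

    for op_idx in range(cfg.n_operons):
        contig = f"contig{op_idx + 1}"
        pos = 1 + int(rng.integers(0, 500))
        op_entry = {
            "contig_id": contig,
            "genes": {},
            "repeats": {},
            "repeat_spans": {},
            "gaps": [],
        }
        for gi, (hmm, role) in enumerate(zip(_FAP_ORDER, _FAP_ROLES)):
            gene_id = f"{cfg.genome_id}_{contig}_g{gi + 1}"
            if role in ("fapB", "fapC"):
                n_rep = reps_B[op_idx] if role == "fapB" else reps_C[op_idx]
                spans = _repeat_layout(cfg, n_rep)
                aa_len = (spans[-1][1] if spans else cfg.repeat_start_aa) + 30
                seq = list(_random_protein(rng, aa_len))
                for k, (a, b) in enumerate(spans):
                    rep_seq = synth_repeat_set(pfm, 1, rng)[0]
                    rep_seq = (rep_seq.replace("-", "A") + "A" * (b - a + 1))[: b - a + 1]
                    seq[a - 1 : b] = list(rep_seq)
                    dom_rows.append(
                        dict(
                            target=gene_id, tlen=aa_len, query="FapBC_repeat", qlen=39,
                            evalue=cfg.hit_evalue, score=120.0 + 5 * n_rep,
                            dom=k + 1, ndom=n_rep,
                            ali_from=a, ali_to=b,
                        )
                    )
                protein = "".join(seq)
                op_entry["repeats"][role] = n_rep
                op_entry["repeat_spans"][role] = spans
            else:
                aa_len = _GENE_AA[role]
                protein = _random_protein(rng, aa_len)
                dom_rows.append(
                    dict(
                        target=gene_id, tlen=aa_len, query=hmm, qlen=aa_len,
                        evalue=cfg.hit_evalue, score=200.0,
                        dom=1, ndom=1, ali_from=5, ali_to=aa_len - 5,
                    )
                )
            bp_len = aa_len * 3 + 3
            genes.append(
                GeneRecord(
                    gene_id=gene_id, genome_id=cfg.genome_id, contig_id=contig,
                    start_bp=pos, end_bp=pos + bp_len - 1,
                    strand="+", protein_length_aa=aa_len,
                )
            )
            fasta_chunks.append(f">{gene_id}\n{protein}\n")
            op_entry["genes"][role] = gene_id
            if gi < len(_FAP_ORDER) - 1:
                gap = cfg.gap_overrides.get((op_idx, gi), cfg.intergenic_gap_bp)
                op_entry["gaps"].append(gap)
                pos = pos + bp_len + gap
        manifest["operons"].append(op_entry)

    if cfg.n_decoys:
        contig = "contig_decoy"
        pos = 1
        for d in range(cfg.n_decoys):
            gene_id = f"{cfg.genome_id}_decoy_g{d + 1}"
            aa_len = int(rng.integers(100, 400))
            bp_len = aa_len * 3 + 3
            genes.append(
                GeneRecord(
                    gene_id=gene_id, genome_id=cfg.genome_id, contig_id=contig,
                    start_bp=pos, end_bp=pos + bp_len - 1,
                    strand="+", protein_length_aa=aa_len,
                )
            )
            fasta_chunks.append(f">{gene_id}\n{_random_protein(rng, aa_len)}\n")
            hmm = str(rng.choice(list(_FAP_ORDER)))
            dom_rows.append(
                dict(
                    target=gene_id, tlen=aa_len, query=hmm, qlen=100,
                    evalue=cfg.decoy_evalue, score=8.0,
                    dom=1, ndom=1, ali_from=10, ali_to=min(60, aa_len),
                )
            )
            manifest["decoys"].append(gene_id)
            pos += bp_len + 10_000  # decoys never chain into clusters

    return SynthGenome(
        genes=genes,
        domtblout_text=write_domtblout(dom_rows),
        fasta_text="".join(fasta_chunks),
        manifest=manifest,
    )


def write_domtblout(rows: list[dict]) -> str:
    """Serialize hit rows in the HMMER3 per-domain tabular dialect.

    Each row dict carries target/tlen/query/qlen/evalue/score/dom/ndom/
    ali_from/ali_to; the remaining columns are filled with plausible values.
    Round-trips through :func:`fapkit.operon.parse_domtblout`.
    """
    lines = [
        "#                                                                            --- full sequence --- -------------- this domain -------------   hmm coord   ali coord   env coord",
        "# target name        accession   tlen query name           accession   qlen   E-value  score  bias   #  of  c-Evalue  i-Evalue  score  bias  from    to  from    to  from    to  acc description of target",
        "#------------------- ---------- ----- -------------------- ---------- ----- --------- ------ ----- --- --- --------- --------- ------ ----- ----- ----- ----- ----- ----- ----- ---- ---------------------",
    ]
    for r in rows:
        dom_score = r.get("dom_score", r["score"] / max(r["ndom"], 1))
        lines.append(
            f"{r['target']:<20} -          {r['tlen']:>5} {r['query']:<20} -          "
            f"{r['qlen']:>5} {r['evalue']:>9.2g} {r['score']:>6.1f}   0.1 "
            f"{r['dom']:>3} {r['ndom']:>3} {r.get('c_evalue', r['evalue']):>9.2g} "
            f"{r.get('i_evalue', r['evalue']):>9.2g} {dom_score:>6.1f}   0.1 "
            f"{1:>5} {r['qlen']:>5} {r['ali_from']:>5} {r['ali_to']:>5} "
            f"{max(1, r['ali_from'] - 3):>5} {r['ali_to'] + 3:>5} 0.95 synthetic gene"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# repeat sequences

#: Consensus tokens of the conserved final 27 positions of the FapC repeat:
#: capitals = complete conservation, lowercase = high, PSI = hydrophobic,
#: tuples = evenly split residues, "*" = unconserved.
FAPC_MOTIF_TOKENS: tuple = (
    "g", "a", "s", "G", "N", "PSI", "G", "PSI", "N", "PSI", "a", "a", "G",
    "*", "g", "N", "q", "Q", "*", "N", "*", "PSI", ("a", "s"), "PSI",
    ("a", "s"), "*", ("a", "s", "g"),
)


def fapc_like_pfm(tokens: tuple = FAPC_MOTIF_TOKENS) -> PFM:
    """Build a position-frequency matrix realizing a consensus-token string.

    Complete-conservation columns put 0.98 on the named residue; high
    conservation 0.75; hydrophobic columns spread 0.88 over four core
    hydrophobics; (x/y[/z]) columns split evenly.  Leftover mass goes to a
    few alternative residues rather than a uniform smear — real repeat
    columns substitute among a handful of residues, and narrow support also
    keeps the sampling variance of rebuilt frequencies small.  '*' columns
    are even over eight mixed residues (no class reaches any threshold).
    """
    aa_index = {a: i for i, a in enumerate(AMINO_ACIDS)}

    def spread(col, mass, residues):
        for a in residues:
            col[aa_index[a]] += mass / len(residues)

    cols = []
    for tok in tokens:
        col = np.zeros(len(AMINO_ACIDS))
        if tok == "*":
            spread(col, 1.0, "ADGK")
        elif tok == "PSI":
            spread(col, 0.88, "AVL")  # hydrophobic core positions
            spread(col, 0.12, "GS")
        elif isinstance(tok, tuple):
            named = [a.upper() for a in tok]
            spread(col, 0.88, named)
            spread(col, 0.12, [a for a in "GNT" if a not in named][:2])
        else:
            main = 0.98 if tok.isupper() else 0.75
            col[aa_index[tok.upper()]] = main
            alts = [a for a in "SGAN" if a != tok.upper()][:2]
            spread(col, 1.0 - main, alts)
        cols.append(col / col.sum())
    freqs = np.array(cols)
    return PFM(freqs=freqs, gap_fraction=np.zeros(len(cols)), label="fapc_like")


def synth_repeat_set(pfm: PFM, n: int, seed_or_rng) -> list[str]:
    """Sample ``n`` sequences column-independently from a PFM.

    Columns emit '-' with probability equal to their gap fraction, otherwise
    a residue drawn from the column's frequency vector.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    letters = np.array(list(AMINO_ACIDS))
    seqs = []
    for _ in range(n):
        chars = []
        for j in range(pfm.n_columns):
            if pfm.gap_fraction[j] > 0 and rng.random() < pfm.gap_fraction[j]:
                chars.append("-")
            else:
                chars.append(str(rng.choice(letters, p=pfm.freqs[j])))
        seqs.append("".join(chars))
    return seqs


# ---------------------------------------------------------------------------
# scattering, helices, profiles


def synth_saxs_curve(
    p: CylinderParams,
    noise_frac: float,
    q_grid,
    seed: int,
) -> SAXSCurve:
    """Forward-model curve with multiplicative Gaussian noise.

    I = I_model · (1 + ε), ε ~ N(0, noise_frac); σ = noise_frac · I_model.
    With noise_frac = 0 the curve is exact and σ is floored at 1e-6 · I to
    keep the curve's positivity invariant.
    """
    if noise_frac < 0:
        raise ValueError("noise_frac must be nonnegative")
    q = np.atleast_1d(np.asarray(q_grid, dtype=float))
    I0 = model_intensity(q, p)
    rng = np.random.default_rng(seed)
    if noise_frac > 0:
        I = I0 * (1.0 + rng.normal(0.0, noise_frac, size=len(q)))
        sigma = noise_frac * np.abs(I0)
    else:
        I = I0
        sigma = np.maximum(1e-6 * np.abs(I0), 1e-30)
    return SAXSCurve(q=q, I=I, sigma=sigma)


def synth_helical_trace(
    p: HelicalParams,
    n_layers: int,
    atoms_per_layer: int = 20,
    seed: int = 0,
) -> tuple[AtomicModel, HelicalParams]:
    """Pseudo-atom fibril: a planar layer motif stacked by screw symmetry.

    The layer motif traces an arc of varying radius in the z = 0 plane
    (a crude stand-in for one cross-β layer); ``n_layers`` copies are
    stacked with the symmetry ``p``.  Returns the model together with the
    ground-truth symmetry.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    if atoms_per_layer < 3:
        raise ValueError("atoms_per_layer must be >= 3")
    rng = np.random.default_rng(seed)
    theta = np.linspace(0.0, np.deg2rad(300.0), atoms_per_layer)
    radius = 9.0 + 3.0 * np.cos(2.5 * theta) + rng.normal(0.0, 0.3, atoms_per_layer)
    layer = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), np.zeros(atoms_per_layer)]
    )
    monomer = AtomicModel(
        coords=layer,
        elements=["C"] * atoms_per_layer,
        chain_ids=["A"] * atoms_per_layer,
        residue_ids=list(range(1, atoms_per_layer + 1)),
        residue_names=["GLY"] * atoms_per_layer,
        f=np.full(atoms_per_layer, 10.0),
    )
    return build_helical_assembly(monomer, p, n_layers), p


def synth_height_profile(
    period_nm: float,
    amplitude_nm: float = 1.0,
    noise_sd_nm: float = 0.2,
    length_nm: float = 1000.0,
    dx_nm: float = 2.0,
    seed: int = 0,
    baseline_nm: float = 2.2,
) -> tuple[HeightProfile, float]:
    """Sinusoidally modulated fibril height trace with additive noise.

    Emulates the ≈1 nm height modulation of a twisted fibril.  The phase is
    random (seeded).  Sampling must resolve the period (dx < period/4).
    Returns the profile and the ground-truth period.
    """
    if period_nm <= 0 or length_nm <= 0 or dx_nm <= 0:
        raise ValueError("period, length and dx must be positive")
    if not dx_nm < period_nm / 4.0:
        raise ValueError(
            f"dx = {dx_nm} nm would alias a {period_nm} nm period (need dx < period/4)"
        )
    rng = np.random.default_rng(seed)
    x = np.arange(0.0, length_nm, dx_nm)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    h = (
        baseline_nm
        + amplitude_nm * np.sin(2.0 * np.pi * x / period_nm + phase)
        + rng.normal(0.0, noise_sd_nm, size=len(x))
    )
    return HeightProfile(position=x, height=h), period_nm
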