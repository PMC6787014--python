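"""Seeded synthetic inputs with known ground truth for every pipeline stage.

No raw patient data accompany the study design this package implements, so
every downstream stage is exercised on simulated material that emulates the
real inputs' structure:

* tissue rasters — non-overlapping disk "vessels" plus cell centroids drawn
  from an inhomogeneous point process whose intensity decays exponentially
  with distance to the nearest vessel border, rho(d) = rho0 * exp(-d/lambda);
* toy transcriptomes — random in-frame coding sequences with planted
  synonymous/missense SNVs, FPKM values, and an HLA typing, together with a
  brute-force truth list of the neo-epitopes that must pass the filter;
* clone repertoires — uniform/geometric/power-law clone frequencies with a
  controlled nonproductive fraction, with directly recomputed truth
  statistics;
* qPCR Ct tables — planted between-group cycle shifts on top of a
  housekeeping baseline.

Each generator consumes a single integer seed and is byte-reproducible.
The genome truth list is computed by an independent brute-force oracle
(own codon table, enumeration over ALL mutant-protein 9-mers) so pipeline
tests never compare the implementation against itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .antigenicity import (
    CodingVariant,
    EpitopeScorer,
    HlaTyping,
    MockEpitopeScorer,
    TranscriptCDS,
)
from .spatial_til import TissueSample
from .tcr_repertoire import Clone, Repertoire, RepertoireStats

__all__ = [
    "SpatialSimParams",
    "GenomeSimParams",
    "RepertoireSimParams",
    "QpcrSimParams",
    "TissueTruth",
    "VariantSetBundle",
    "generate_tissue",
    "generate_variant_set",
    "generate_repertoire",
    "generate_qpcr",
    "brute_force_neoepitopes",
    "translate_simple",
]

UM2_PER_MM2 = 1e6
_VESSEL_PLACEMENT_RETRIES = 2000

# ---------------------------------------------------------------------------
# parameter blocks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpatialSimParams:
    image_size_px: tuple[int, int] = (1200, 1200)  # (rows, cols)
    pixel_size_um: float = 0.5
    n_vessels: int = 3
    vessel_radius_um: tuple[float, float] = (15.0, 30.0)
    baseline_density_per_mm2: float = 500.0
    decay_length_um: float | None = 40.0  # None disables the decay
    max_annulus_um: float = 180.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vessels < 1:
            raise ValueError("n_vessels must be >= 1")
        if self.pixel_size_um <= 0 or self.baseline_density_per_mm2 <= 0:
            raise ValueError("pixel size and baseline density must be positive")
        if self.decay_length_um is not None and self.decay_length_um <= 0:
            raise ValueError("decay_length_um must be positive (or None)")
        lo, hi = self.vessel_radius_um
        if not (0 < lo <= hi):
            raise ValueError("vessel_radius_um must be a positive (lo, hi) range")
        min_dim_um = min(self.image_size_px) * self.pixel_size_um
        if min_dim_um < 2 * (hi + self.max_annulus_um):
            raise ValueError(
                "image too small for the outermost annulus to fit around a vessel"
            )


@dataclass(frozen=True)
class GenomeSimParams:
    n_transcripts: int = 10
    cds_length_codons: tuple[int, int] = (60, 200)  # incl. start and stop codon
    n_variants: int = 8
    fraction_synonymous: float = 0.3
    fraction_expressed: float = 0.7
    hla_alleles: tuple[str, ...] = ("A*02:01", "B*07:02", "C*07:01")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 0 or self.n_transcripts < 1:
            raise ValueError("need >= 1 transcript and >= 0 variants")
        if not (0 <= self.fraction_synonymous <= 1):
            raise ValueError("fraction_synonymous must be in [0, 1]")
        if not (0 <= self.fraction_expressed <= 1):
            raise ValueError("fraction_expressed must be in [0, 1]")
        lo, hi = self.cds_length_codons
        if lo < 4 or hi < lo:
            raise ValueError("cds_length_codons must be a range with lo >= 4")


@dataclass(frozen=True)
class RepertoireSimParams:
    n_clones: int = 50
    frequency_model: str = "geometric"  # uniform | geometric | powerlaw
    model_parameter: float = 0.1
    nonproductive_fraction: float = 0.15
    total_reads: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if self.total_reads < self.n_clones:
            raise ValueError("total_reads must be >= n_clones")
        if self.frequency_model not in ("uniform", "geometric", "powerlaw"):
            raise ValueError(f"unknown frequency_model {self.frequency_model!r}")
        if not (0 <= self.nonproductive_fraction <= 1):
            raise ValueError("nonproductive_fraction must be in [0, 1]")


@dataclass(frozen=True)
class QpcrSimParams:
    genes: tuple[str, ...] = ("CXCL9", "CXCL10", "ICAM1", "GZMK")
    n_per_group: tuple[int, int] = (20, 20)
    group_delta_ct_shift: Mapping[str, float] | float = 0.0  # added to group B
    ct_noise_sd: float = 0.5
    housekeeping_ct_mean: float = 20.0
    baseline_delta_ct: float = 5.0  # target genes sit above the housekeeper
    housekeeping_gene: str = "GAPDH"
    group_labels: tuple[str, str] = ("LGG", "HGG")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_per_group) < 1:
            raise ValueError("n_per_group must be >= 1 in each group")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be >= 0")

    def shift_for(self, gene: str) -> float:
        if isinstance(self.group_delta_ct_shift, Mapping):
            return float(self.group_delta_ct_shift.get(gene, 0.0))
        return float(self.group_delta_ct_shift)


# ---------------------------------------------------------------------------
# tissue generator
# ---------------------------------------------------------------------------


@dataclass
class TissueTruth:
    """Ground truth behind a simulated tissue raster."""

    decay_length_um: float | None
    baseline_density_per_mm2: float
    vessel_centers_px: np.ndarray
    vessel_radii_um: np.ndarray
    expected_annulus_density: np.ndarray  # rho0 * exp(-d_mid / lambda)
    bin_edges_um: np.ndarray


def generate_tissue(
    params: SpatialSimParams, bin_width_um: float = 30.0
) -> tuple[TissueSample, TissueTruth]:
    """Simulate a vessel mask and a perivascularly decaying cell pattern.

    Vessels are non-overlapping disks whose centers keep the full outermost
    annulus inside the image. Cells come from thinning a homogeneous
    Poisson process of rate rho0: a point at distance d (um) from the
    nearest vessel border survives with probability exp(-d/lambda), and
    points inside vessel lumina are always rejected. With
    ``decay_length_um=None`` the thinning is disabled and the pattern is
    uniform outside vessels.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size_px
    px = params.pixel_size_um

    margin_um = params.max_annulus_um
    centers: list[tuple[float, float]] = []
    radii_um: list[float] = []
    for _ in range(params.n_vessels):
        placed = False
        for _ in range(_VESSEL_PLACEMENT_RETRIES):
            r_um = rng.uniform(*params.vessel_radius_um)
            pad_px = (r_um + margin_um) / px
            cy = rng.uniform(pad_px, h - pad_px)
            cx = rng.uniform(pad_px, w - pad_px)
            ok = all(
                np.hypot(cy - oy, cx - ox) * px > r_um + orad + 2 * px
                for (oy, ox), orad in zip(centers, radii_um)
            )
            if ok:
                centers.append((cy, cx))
                radii_um.append(r_um)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place {params.n_vessels} non-overlapping vessels "
                f"in a {h}x{w} px image after {_VESSEL_PLACEMENT_RETRIES} tries"
            )

    yy, xx = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    for (cy, cx), r_um in zip(centers, radii_um):
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= (r_um / px) ** 2

    dist_um = ndimage.distance_transform_edt(~mask) * px

    area_mm2 = h * w * px**2 / UM2_PER_MM2
    n_candidates = rng.poisson(params.baseline_density_per_mm2 * area_mm2)
    cand_x = rng.uniform(0, w, size=n_candidates)
    cand_y = rng.uniform(0, h, size=n_candidates)
    ci = np.minimum(cand_y.astype(int), h - 1)
    cj = np.minimum(cand_x.astype(int), w - 1)
    d = dist_um[ci, cj]
    inside = mask[ci, cj]
    if params.decay_length_um is None:
        accept = ~inside
    else:
        accept = (~inside) & (
            rng.uniform(size=n_candidates) < np.exp(-d / params.decay_length_um)
        )

    cells = pd.DataFrame(
        {"x_px": cand_x[accept], "y_px": cand_y[accept], "marker": "CD3"}
    )
    sample = TissueSample(
        vessel_mask=mask,
        cells=cells,
        pixel_size_um=px,
        sample_id=f"sim-{params.seed}",
    )

    edges = np.arange(0, params.max_annulus_um + bin_width_um, bin_width_um)
    mids = (edges[:-1] + edges[1:]) / 2
    if params.decay_length_um is None:
        expected = np.full(mids.size, params.baseline_density_per_mm2)
    else:
        expected = params.baseline_density_per_mm2 * np.exp(
            -mids / params.decay_length_um
        )
    truth = TissueTruth(
        decay_length_um=params.decay_length_um,
        baseline_density_per_mm2=params.baseline_density_per_mm2,
        vessel_centers_px=np.array(centers),
        vessel_radii_um=np.array(radii_um),
        expected_annulus_density=expected,
        bin_edges_um=edges,
    )
    return sample, truth


# ---------------------------------------------------------------------------
# genome / variant generator with independent brute-force truth
# ---------------------------------------------------------------------------

# Independent standard-code codon table (used only by the oracle), kept
# separate from the Biopython translation the pipeline uses.
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
_STOP_CODONS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = [c for c, aa in _CODON_TABLE.items() if aa != "*"]


def translate_simple(cds: str) -> str:
    """Table-driven translation to the first stop; independent of Biopython."""
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        aa = _CODON_TABLE[cds[i : i + 3]]
        if aa == "*":
            break
        aas.append(aa)
    return "".join(aas)


@dataclass
class VariantSetBundle:
    """A synthetic sample's genome inputs plus the brute-force truth."""

    transcripts: dict[str, TranscriptCDS]
    variants: list[CodingVariant]
    expression: dict[str, float]  # gene_id -> FPKM
    typing: HlaTyping
    intended_consequences: list[str]
    truth_passing: set[tuple[str, str]] = field(default_factory=set)
    truth_count: int = 0


def brute_force_neoepitopes(
    transcripts: Mapping[str, TranscriptCDS],
    variants: Sequence[CodingVariant],
    expression: Mapping[str, float],
    typing: HlaTyping,
    scorer: EpitopeScorer | None = None,
    score_threshold: float = 0.5,
    fpkm_threshold: float = 0.0,
) -> set[tuple[str, str]]:
    """Exhaustive oracle: passing (peptide, allele) pairs, no windowing.

    Translates each mutant CDS with its own codon table, enumerates every
    9-mer of the entire mutant protein, keeps those whose span covers the
    mutated residue and whose amino acid actually changed, then applies the
    same strict expression and three-score filters as the pipeline.
    """
    scorer = scorer or MockEpitopeScorer()
    passing: set[tuple[str, str]] = set()
    for v in variants:
        tx = transcripts[v.transcript_id]
        cds = tx.cds_sequence
        pos0 = v.cds_position - 1
        assert cds[pos0] == v.ref_base
        mut_cds = cds[:pos0] + v.alt_base + cds[pos0 + 1 :]
        codon_idx = pos0 // 3
        ref_aa = _CODON_TABLE[cds[codon_idx * 3 : codon_idx * 3 + 3]]
        alt_aa = _CODON_TABLE[mut_cds[codon_idx * 3 : codon_idx * 3 + 3]]
        if ref_aa == alt_aa or alt_aa == "*" or ref_aa == "*":
            continue  # not a simple missense: no mutated-residue 9-mers
        mut_protein = translate_simple(mut_cds)
        if codon_idx >= len(mut_protein):
            continue  # mutation beyond an upstream stop
        if float(expression.get(tx.gene_id, 0.0)) <= fpkm_threshold:
            continue
        for s in range(len(mut_protein) - 8):
            if not (s <= codon_idx <= s + 8):
                continue
            peptide = mut_protein[s : s + 9]
            for allele in typing.alleles:
                b, c, t = scorer.score(peptide, allele)
                if b > score_threshold and c > score_threshold and t > score_threshold:
                    passing.add((peptide, allele))
    return passing


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(_SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(_STOP_CODONS)
    return "ATG" + "".join(body) + stop


def generate_variant_set(
    params: GenomeSimParams, sample_id: str = "sim"
) -> VariantSetBundle:
    """Random transcriptome with planted SNVs and brute-force epitope truth.

    Variants are planted at distinct codon positions; each is forced to the
    intended consequence (synonymous with probability
    ``fraction_synonymous``, otherwise missense) by choosing an alternate
    base that produces it. Expression assigns a log-normal FPKM to a
    ``fraction_expressed`` share of transcripts and exactly 0 to the rest.
    """
    rng = np.random.default_rng(params.seed)
    transcripts: dict[str, TranscriptCDS] = {}
    for i in range(params.n_transcripts):
        n_codons = int(rng.integers(*params.cds_length_codons, endpoint=True))
        tid = f"TX{i:04d}"
        transcripts[tid] = TranscriptCDS(
            transcript_id=tid, cds_sequence=_random_cds(rng, n_codons),
            gene_id=f"GENE{i:04d}",
        )

    # candidate codon positions: internal codons only (not start, not stop)
    positions = [
        (tid, codon)
        for tid, tx in transcripts.items()
        for codon in range(1, len(tx.cds_sequence) // 3 - 1)
    ]
    if params.n_variants > len(positions):
        raise ValueError(
            f"requested {params.n_variants} variants but only "
            f"{len(positions)} codon positions are available"
        )
    def _options(tid: str, codon: int, want_syn: bool):
        cds = transcripts[tid].cds_sequence
        codon_seq = cds[codon * 3 : codon * 3 + 3]
        ref_aa = _CODON_TABLE[codon_seq]
        opts = []
        for off in range(3):
            for alt in "ACGT":
                if alt == codon_seq[off]:
                    continue
                alt_aa = _CODON_TABLE[codon_seq[:off] + alt + codon_seq[off + 1 :]]
                if want_syn and alt_aa == ref_aa:
                    opts.append((off, alt, "synonymous"))
                elif not want_syn and alt_aa not in ("*", ref_aa):
                    opts.append((off, alt, "missense"))
        return opts

    order = rng.permutation(len(positions))
    used: set[int] = set()
    variants: list[CodingVariant] = []
    intended: list[str] = []
    for _ in range(params.n_variants):
        want_syn = rng.uniform() < params.fraction_synonymous
        placed = False
        # first unused codon position that admits the intended consequence
        # (e.g. ATG and TGG codons cannot mutate synonymously)
        for k in order:
            if k in used:
                continue
            tid, codon = positions[k]
            options = _options(tid, codon, want_syn)
            if not options:
                continue
            used.add(k)
            off, alt, consequence = options[rng.integers(len(options))]
            pos = codon * 3 + off + 1  # 1-based CDS coordinate
            cds = transcripts[tid].cds_sequence
            variants.append(
                CodingVariant(
                    transcript_id=tid,
                    cds_position=pos,
                    ref_base=cds[pos - 1],
                    alt_base=alt,
                    sample_id=sample_id,
                )
            )
            intended.append(consequence)
            placed = True
            break
        if not placed:
            raise ValueError(
                "no remaining codon position admits the requested variant "
                "consequence; lower n_variants or enlarge the transcriptome"
            )

    n_expressed = int(round(params.fraction_expressed * params.n_transcripts))
    expressed_idx = set(
        rng.choice(params.n_transcripts, size=n_expressed, replace=False).tolist()
    )
    expression = {
        tx.gene_id: float(rng.lognormal(mean=1.0, sigma=1.0)) if i in expressed_idx
        else 0.0
        for i, (tid, tx) in enumerate(transcripts.items())
    }

    typing = HlaTyping(sample_id=sample_id, alleles=tuple(params.hla_alleles))
    truth = brute_force_neoepitopes(transcripts, variants, expression, typing)
    return VariantSetBundle(
        transcripts=transcripts,
        variants=variants,
        expression=expression,
        typing=typing,
        intended_consequences=intended,
        truth_passing=truth,
        truth_count=len(truth),
    )


# ---------------------------------------------------------------------------
# repertoire generator
# ---------------------------------------------------------------------------

_NT = np.array(list("ACGT"))


def _random_cdr3(rng: np.random.Generator, productive: bool) -> tuple[str, str]:
    """Random in-frame CDR3 nucleotide sequence and its translation.

    Nonproductive rearrangements carry a premature stop codon, mirroring
    the productive/nonproductive dichotomy of rearranged receptor loci.
    """
    n_codons = int(rng.integers(10, 17))
    codons = [
        _SENSE_CODONS[rng.integers(len(_SENSE_CODONS))] for _ in range(n_codons)
    ]
    if not productive:
        stop_at = int(rng.integers(1, n_codons - 1))
        codons[stop_at] = _STOP_CODONS[rng.integers(3)]
    nt = "".join(codons)
    aa = "".join(_CODON_TABLE[nt[i : i + 3]] for i in range(0, len(nt), 3))
    return nt, aa


def generate_repertoire(
    params: RepertoireSimParams, sample_id: str = "sim", group: str = ""
) -> tuple[Repertoire, RepertoireStats]:
    """Sample a clone table and recompute its truth statistics directly.

    Clone frequencies follow the chosen model (uniform; geometric with
    success probability ``model_parameter``; power law with exponent
    ``model_parameter``), reads are multinomial with one guaranteed read
    per clone, and ``nonproductive_fraction`` of clones get an in-frame
    stop. Truth stats are prefix sums on the emitted counts, independent
    of the analysis module.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_clones

    ranks = np.arange(1, n + 1, dtype=float)
    if params.frequency_model == "uniform":
        probs = np.full(n, 1.0 / n)
    elif params.frequency_model == "geometric":
        p = params.model_parameter
        if not (0 < p < 1):
            raise ValueError("geometric model_parameter must be in (0, 1)")
        probs = p * (1 - p) ** (ranks - 1)
    else:  # powerlaw
        alpha = params.model_parameter
        if alpha <= 0:
            raise ValueError("powerlaw model_parameter must be > 0")
        probs = ranks**-alpha
    probs = probs / probs.sum()

    counts = np.ones(n, dtype=int)
    if params.total_reads > n:
        counts += rng.multinomial(params.total_reads - n, probs)

    n_nonproductive = int(round(params.nonproductive_fraction * n))
    nonproductive = np.zeros(n, dtype=bool)
    if n_nonproductive:
        nonproductive[
            rng.choice(n, size=n_nonproductive, replace=False)
        ] = True

    clones: list[Clone] = []
    seen_nt: set[str] = set()
    for i in range(n):
        for _ in range(1000):
            nt, aa = _random_cdr3(rng, productive=not nonproductive[i])
            if nt not in seen_nt:
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not draw a unique CDR3")
        seen_nt.add(nt)
        clones.append(
            Clone(
                cdr3_nt=nt,
                cdr3_aa=aa,
                read_count=int(counts[i]),
                productive=not nonproductive[i],
            )
        )
    rep = Repertoire(sample_id=sample_id, group=group, clones=clones)

    # --- truth by direct prefix-sum computation on the emitted table ---
    prod = sorted(
        (c for c in clones if c.productive),
        key=lambda c: (-c.read_count, c.cdr3_nt),
    )
    prod_reads = sum(c.read_count for c in prod)
    k = len(prod)
    cum = 0
    for i, c in enumerate(prod, 1):
        cum += c.read_count
        if cum >= 0.30 * prod_reads:
            k = i
            break
    top10 = 100.0 * sum(c.read_count for c in prod[:10]) / prod_reads if prod else 0.0
    truth = RepertoireStats(
        sample_id=sample_id,
        group=group,
        total_reads=int(counts.sum()),
        productive_frequency_pct=100.0 * (n - n_nonproductive) / n,
        dominant_clone_count=k,
        top10_abundance_pct=top10,
    )
    return rep, truth


# ---------------------------------------------------------------------------
# qPCR generator
# ---------------------------------------------------------------------------


def generate_qpcr(params: QpcrSimParams) -> pd.DataFrame:
    """Long-format Ct table with a planted between-group cycle shift.

    Every sample carries one housekeeping row; target genes sit
    ``baseline_delta_ct`` cycles above the housekeeper in group A and are
    shifted by ``group_delta_ct_shift`` additional cycles in group B (a
    positive shift means lower expression there: +3 cycles is an 8-fold
    drop in 2^-dCt). Gaussian noise of sd ``ct_noise_sd`` is added to
    every target Ct; the housekeeping Ct is noise-free so that planted
    shifts translate exactly into relative-expression ratios.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    _, label_b = params.group_labels
    for label, n in zip(params.group_labels, params.n_per_group):
        for s in range(n):
            sid = f"{label}-{s + 1:02d}"
            hk_ct = params.housekeeping_ct_mean
            rows.append(
                {"sample_id": sid, "group": label,
                 "gene": params.housekeeping_gene, "ct": hk_ct}
            )
            for gene in params.genes:
                ct = (
                    params.housekeeping_ct_mean
                    + params.baseline_delta_ct
                    + (params.shift_for(gene) if label == label_b else 0.0)
                    + rng.normal(0.0, params.ct_noise_sd)
                )
                rows.append(
                    {"sample_id": sid, "group": label, "gene": gene, "ct": ct}
                )
    return pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"])
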