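"""Neo-epitope candidate enumeration from coding SNVs.

A somatic single-nucleotide variant is edited into its transcript's coding
sequence, both alleles are translated, and for missense changes a 17-residue
window centred on the mutated amino acid is tiled into 9-mers. Every 9-mer
that covers the mutation is scored per HLA class-I allele on three channels
(MHC binding, proteasomal C-terminal cleavage, TAP transport efficiency)
and kept as a candidate neo-epitope when it comes from an expressed gene
(FPKM > 0) and all three scores exceed 0.5 (strict). Also here: counts of
expressed nonsynonymous mutations and of expressed cancer germline antigens
(CGAs) per sample.

The epitope scorer is pluggable: production use wraps an external predictor
such as NetCTLpan; tests and synthetic runs use a deterministic hash-based
mock with the same interface.
"""

from __future__ import annotations

import hashlib
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Protocol, Sequence

import pandas as pd
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptCDS",
    "CodingVariant",
    "MutantWindow",
    "EpitopeCandidate",
    "HlaTyping",
    "EpitopeScorer",
    "MockEpitopeScorer",
    "build_mutant_protein",
    "extract_window",
    "enumerate_9mers",
    "score_candidates",
    "filter_neoepitopes",
    "neoepitope_pipeline",
    "count_expressed_mutations",
    "count_expressed_cgas",
    "load_bundled_cga_list",
]

WINDOW_SIZE = 17
EPITOPE_LENGTH = 9
DEFAULT_SCORE_THRESHOLD = 0.5
DEFAULT_FPKM_THRESHOLD = 0.0

STOP = "*"
_HLA_RE = re.compile(r"^[A-Z]+\*\d+:\d+$")
_NT_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class TranscriptCDS:
    """A coding sequence, 5'->3', in frame (ATG ... stop)."""

    transcript_id: str
    cds_sequence: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        seq = self.cds_sequence.upper()
        object.__setattr__(self, "cds_sequence", seq)
        if not _NT_RE.match(seq):
            raise ValueError(
                f"{self.transcript_id}: CDS contains non-ACGT characters"
            )
        if len(seq) % 3:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(seq)} not a multiple of 3"
            )
        if not seq.startswith("ATG"):
            raise ValueError(f"{self.transcript_id}: CDS does not start with ATG")


@dataclass(frozen=True)
class CodingVariant:
    """A somatic SNV in transcript (CDS) coordinates, 1-based."""

    transcript_id: str
    cds_position: int  # 1-based nucleotide index
    ref_base: str
    alt_base: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.cds_position < 1:
            raise ValueError("cds_position is 1-based and must be >= 1")
        for b, name in ((self.ref_base, "ref"), (self.alt_base, "alt")):
            if b not in "ACGT":
                raise ValueError(f"{name} base must be one of A/C/G/T, got {b!r}")


@dataclass(frozen=True)
class MutantWindow:
    """Peptide window around a mutated residue (<= 17 aa after truncation)."""

    peptide: str
    mutated_index: int  # 0-based within the window
    protein_position: int  # 1-based in the mutant protein
    consequence: str
    transcript_id: str = ""
    gene_id: str = ""
    sample_id: str = ""


@dataclass(frozen=True)
class EpitopeCandidate:
    """A scored 9-mer x HLA-allele pair with its filter verdict."""

    peptide_9mer: str
    hla_allele: str
    mhc_binding_score: float
    cleavage_score: float
    tap_score: float
    gene_id: str
    fpkm: float
    contains_mutation: bool
    passes: bool
    sample_id: str = ""


@dataclass(frozen=True)
class HlaTyping:
    """Up to six class-I alleles at 4-digit resolution (e.g. A*02:01)."""

    sample_id: str
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = [a for a in self.alleles if not _HLA_RE.match(a)]
        if bad:
            raise ValueError(f"malformed HLA allele name(s): {bad}")


class EpitopeScorer(Protocol):
    """Deterministic scorer: (peptide, allele) -> (binding, cleavage, TAP)."""

    def score(self, peptide: str, allele: str) -> tuple[float, float, float]: ...


class MockEpitopeScorer:
    """Hash-based stand-in scorer with the production interface.

    Each of the three channels maps SHA-256 of ``peptide|allele|channel`` to
    a uniform-looking value in [0, 1). Deterministic across processes and
    platforms, which makes filter behaviour exactly reproducible without an
    external predictor.
    """

    CHANNELS = ("binding", "cleavage", "tap")

    def score(self, peptide: str, allele: str) -> tuple[float, float, float]:
        out = []
        for channel in self.CHANNELS:
            digest = hashlib.sha256(
                f"{peptide}|{allele}|{channel}".encode()
            ).digest()
            out.append(int.from_bytes(digest[:8], "big") / 2**64)
        return tuple(out)  # type: ignore[return-value]


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard code, stopping at the first stop."""
    protein = str(Seq(cds).translate())
    stop_at = protein.find(STOP)
    return protein if stop_at < 0 else protein[:stop_at]


def build_mutant_protein(
    transcript: TranscriptCDS, variant: CodingVariant
) -> tuple[str, str, str, int]:
    """Edit an SNV into the CDS and translate reference and mutant alleles.

    Returns ``(ref_protein, mut_protein, consequence, protein_position)``
    where consequence is one of synonymous / missense / stop_gain /
    stop_loss, judged from the reference vs alternate amino acid at the
    affected codon, and protein_position is the 1-based codon index.
    """
    cds = transcript.cds_sequence
    pos0 = variant.cds_position - 1
    if pos0 >= len(cds):
        raise ValueError(
            f"{transcript.transcript_id}: position {variant.cds_position} "
            f"beyond CDS length {len(cds)}"
        )
    if cds[pos0] != variant.ref_base:
        raise ValueError(
            f"{transcript.transcript_id} position {variant.cds_position}: "
            f"ref base {variant.ref_base!r} does not match CDS "
            f"({cds[pos0]!r})"
        )

    mut_cds = cds[:pos0] + variant.alt_base + cds[pos0 + 1 :]
    codon_idx = pos0 // 3
    ref_aa = str(Seq(cds[codon_idx * 3 : codon_idx * 3 + 3]).translate())
    alt_aa = str(Seq(mut_cds[codon_idx * 3 : codon_idx * 3 + 3]).translate())

    if ref_aa == alt_aa:
        consequence = "synonymous"
    elif alt_aa == STOP:
        consequence = "stop_gain"
    elif ref_aa == STOP:
        consequence = "stop_loss"
    else:
        consequence = "missense"

    return translate_cds(cds), translate_cds(mut_cds), consequence, codon_idx + 1


def extract_window(
    mut_protein: str, protein_position: int, size: int = WINDOW_SIZE
) -> MutantWindow:
    """Cut the peptide window centred on the mutated residue.

    For a mutation deep inside the protein the window is the full ``size``
    residues with the mutation at the middle position; near either terminus
    it is truncated to the protein and the in-window index shifts
    accordingly.
    """
    if size % 2 == 0:
        raise ValueError("window size must be odd so the mutation can be central")
    L = len(mut_protein)
    if not (1 <= protein_position <= L):
        raise ValueError(
            f"protein position {protein_position} outside protein of length {L}"
        )
    half = size // 2
    start = max(1, protein_position - half)  # 1-based, inclusive
    end = min(L, protein_position + half)
    return MutantWindow(
        peptide=mut_protein[start - 1 : end],
        mutated_index=protein_position - start,
        protein_position=protein_position,
        consequence="missense",
    )


def enumerate_9mers(window: MutantWindow) -> list[str]:
    """All distinct 9-mers of the window whose span covers the mutation.

    A window shorter than nine residues yields no candidates (logged).
    """
    L = len(window.peptide)
    if L < EPITOPE_LENGTH:
        logger.warning(
            "window of length %d (< %d) yields no 9-mers", L, EPITOPE_LENGTH
        )
        return []
    peptides: list[str] = []
    seen: set[str] = set()
    for s in range(L - EPITOPE_LENGTH + 1):
        if s <= window.mutated_index <= s + EPITOPE_LENGTH - 1:
            p = window.peptide[s : s + EPITOPE_LENGTH]
            if p not in seen:
                seen.add(p)
                peptides.append(p)
    return peptides


def score_candidates(
    peptides: Sequence[tuple[str, str]],
    typing: HlaTyping,
    scorer: EpitopeScorer,
    expression: Mapping[str, float],
) -> list[EpitopeCandidate]:
    """Score every (peptide, allele) pair and join gene expression.

    ``peptides`` is a sequence of ``(peptide_9mer, gene_id)``; genes absent
    from the expression mapping score FPKM 0 with a log warning. Candidates
    carry raw scores only; the pass verdict is assigned by
    :func:`filter_neoepitopes`.
    """
    candidates = []
    for peptide, gene in peptides:
        if gene not in expression:
            logger.warning("gene %s has no expression value; FPKM set to 0", gene)
        fpkm = float(expression.get(gene, 0.0))
        for allele in typing.alleles:
            binding, cleavage, tap = scorer.score(peptide, allele)
            candidates.append(
                EpitopeCandidate(
                    peptide_9mer=peptide,
                    hla_allele=allele,
                    mhc_binding_score=binding,
                    cleavage_score=cleavage,
                    tap_score=tap,
                    gene_id=gene,
                    fpkm=fpkm,
                    contains_mutation=True,
                    passes=False,
                    sample_id=typing.sample_id,
                )
            )
    return candidates


def filter_neoepitopes(
    candidates: Sequence[EpitopeCandidate],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    fpkm_threshold: float = DEFAULT_FPKM_THRESHOLD,
    counting_unit: str = "peptide_allele",
) -> tuple[list[EpitopeCandidate], int]:
    """Apply the three-score + expression filter and count passing hits.

    A candidate passes iff it contains the mutated residue, its gene is
    expressed (FPKM strictly above ``fpkm_threshold``), and all of the
    binding, cleavage and TAP scores are strictly above
    ``score_threshold``. The count is over distinct (peptide, allele)
    pairs by default, or distinct peptides with
    ``counting_unit='peptide'``.
    """
    if counting_unit not in ("peptide_allele", "peptide"):
        raise ValueError(f"unknown counting_unit {counting_unit!r}")
    verdicts = []
    for c in candidates:
        ok = (
            c.contains_mutation
            and c.fpkm > fpkm_threshold
            and c.mhc_binding_score > score_threshold
            and c.cleavage_score > score_threshold
            and c.tap_score > score_threshold
        )
        verdicts.append(
            EpitopeCandidate(**{**c.__dict__, "passes": ok})
            if ok != c.passes
            else c
        )
    passing = [c for c in verdicts if c.passes]
    if counting_unit == "peptide_allele":
        count = len({(c.peptide_9mer, c.hla_allele) for c in passing})
    else:
        count = len({c.peptide_9mer for c in passing})
    return verdicts, count


def neoepitope_pipeline(
    transcripts: Mapping[str, TranscriptCDS],
    variants: Sequence[CodingVariant],
    expression: Mapping[str, float],
    typing: HlaTyping,
    scorer: EpitopeScorer | None = None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    fpkm_threshold: float = DEFAULT_FPKM_THRESHOLD,
    counting_unit: str = "peptide_allele",
) -> tuple[pd.DataFrame, int]:
    """Variants -> mutant proteins -> windows -> scored, filtered 9-mers.

    Runs the full candidate pipeline for one sample and returns the
    candidate table (one row per peptide x allele, with scores and
    verdicts) plus the passing count in the chosen unit. Synonymous
    variants produce no candidates; stop-gain/stop-loss variants have no
    single mutated-residue 9-mer semantics and are excluded with a log
    message.
    """
    scorer = scorer or MockEpitopeScorer()
    peptide_gene: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for v in variants:
        tx = transcripts.get(v.transcript_id)
        if tx is None:
            raise KeyError(f"variant references unknown transcript {v.transcript_id}")
        _, mut_protein, consequence, pos = build_mutant_protein(tx, v)
        if consequence != "missense":
            if consequence in ("stop_gain", "stop_loss"):
                logger.info(
                    "%s:%d %s excluded from epitope enumeration",
                    v.transcript_id, v.cds_position, consequence,
                )
            continue
        window = extract_window(mut_protein, pos)
        for p in enumerate_9mers(window):
            key = (p, tx.gene_id)
            if key not in seen:
                seen.add(key)
                peptide_gene.append(key)

    candidates = score_candidates(peptide_gene, typing, scorer, expression)
    verdicts, count = filter_neoepitopes(
        candidates, score_threshold, fpkm_threshold, counting_unit
    )
    table = pd.DataFrame([c.__dict__ for c in verdicts])
    if table.empty:
        table = pd.DataFrame(
            columns=[
                "peptide_9mer", "hla_allele", "mhc_binding_score",
                "cleavage_score", "tap_score", "gene_id", "fpkm",
                "contains_mutation", "passes", "sample_id",
            ]
        )
    return table, count


def count_expressed_mutations(
    transcripts: Mapping[str, TranscriptCDS],
    variants: Sequence[CodingVariant],
    expression: Mapping[str, float],
    fpkm_threshold: float = DEFAULT_FPKM_THRESHOLD,
) -> int:
    """Number of nonsynonymous variants whose gene is expressed.

    Nonsynonymous means the reference and alternate amino acids differ
    (missense, stop-gain or stop-loss); expressed means gene FPKM strictly
    above the threshold.
    """
    n = 0
    for v in variants:
        tx = transcripts[v.transcript_id]
        _, _, consequence, _ = build_mutant_protein(tx, v)
        if consequence == "synonymous":
            continue
        if float(expression.get(tx.gene_id, 0.0)) > fpkm_threshold:
            n += 1
    return n


def count_expressed_cgas(
    expression: pd.DataFrame,
    cga_genes: Sequence[str],
    fpkm_threshold: float = DEFAULT_FPKM_THRESHOLD,
) -> pd.Series:
    """Per-sample count of cancer germline antigen genes that are expressed.

    ``expression`` is a long table with columns ``gene, sample, fpkm``.
    Raises when no gene in the catalogue matches the expression matrix at
    all, listing the unmatched identifiers.
    """
    cga_set = set(cga_genes)
    matrix_genes = set(expression["gene"].unique())
    matched = cga_set & matrix_genes
    if not matched:
        raise ValueError(
            "no CGA gene matches the expression matrix; unmatched identifiers: "
            + ", ".join(sorted(cga_set)[:20])
            + ("..." if len(cga_set) > 20 else "")
        )
    sub = expression[expression["gene"].isin(matched)]
    counts = (
        sub.assign(expressed=sub["fpkm"] > fpkm_threshold)
        .groupby("sample")["expressed"]
        .sum()
        .astype(int)
    )
    return counts.reindex(expression["sample"].unique(), fill_value=0)


def load_bundled_cga_list() -> list[str]:
    """Gene symbols from the bundled synthetic CGA catalogue snapshot."""
    text = (
        resources.files("gliomactx")
        .joinpath("data/cga_genes_synthetic_snapshot.txt")
        .read_text()
    )
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]
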