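"""Per-transcript features computed from coding sequences.

Implements the sequence-derived predictors used in the degradation-rate
model: GC content at each codon position (GC1/GC2/GC3, the last being the
wobble position), the codon adaptation index (CAI) of Sharp & Li, a
normalized translational efficiency (nTE) score averaged over codons, and
a poly-proline classification (runs of >= 4 consecutive proline codons,
which slow translation elongation).
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "STOP_CODONS",
    "SENSE_CODONS",
    "SYNONYMOUS_FAMILIES",
    "PROLINE_CODONS",
    "CodingSequence",
    "CodonUsageTable",
    "RejectedRecord",
    "read_fasta",
    "write_fasta",
    "gc_by_codon_position",
    "relative_adaptiveness",
    "cai",
    "nte_score",
    "polyproline_class",
    "read_codon_weights",
    "feature_table",
]

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]

STOP_CODONS = frozenset(_STANDARD_TABLE.stop_codons)  # {TAA, TAG, TGA}
SENSE_CODONS = tuple(sorted(_STANDARD_TABLE.forward_table))  # 61 codons

#: codon -> amino acid for the standard genetic code
CODON_TO_AA: Mapping[str, str] = dict(_STANDARD_TABLE.forward_table)

#: amino acid -> tuple of synonymous codons
SYNONYMOUS_FAMILIES: Mapping[str, tuple[str, ...]] = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in set(CODON_TO_AA.values())
}

#: amino acids encoded by a single codon; their codons carry no usage
#: information and are excluded from CAI (Sharp & Li convention)
SINGLE_CODON_AAS = frozenset(
    aa for aa, codons in SYNONYMOUS_FAMILIES.items() if len(codons) == 1
)  # {M, W} -> ATG, TGG

PROLINE_CODONS = frozenset(SYNONYMOUS_FAMILIES["P"])  # CCA, CCC, CCG, CCT

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class CodingSequence:
    """A protein-coding nucleotide sequence, validated on construction.

    The sequence must be a non-empty multiple of 3 over {A,C,G,T};
    ambiguity codes are rejected so codon-level features are well defined.
    """

    gene_id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) == 0 or len(self.seq) % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: length {len(self.seq)} not a positive multiple of 3"
            )
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"{self.gene_id}: invalid bases {sorted(bad)} (only A/C/G/T allowed)"
            )

    @property
    def codons(self) -> list[str]:
        return [self.seq[i : i + 3] for i in range(0, len(self.seq), 3)]

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class RejectedRecord:
    gene_id: str
    reason: str


@dataclass
class CodonUsageTable:
    """Codon counts and the relative-adaptiveness weights w derived from them.

    w(codon) = (count + pseudo_count) / max over the synonymous family,
    so the most-used codon of every amino-acid family has w = 1. Weights
    are defined for the 61 sense codons only.
    """

    counts: dict[str, float]
    w: dict[str, float] = field(default_factory=dict)


def read_fasta(path: str | Path) -> tuple[list[CodingSequence], list[RejectedRecord]]:
    """Read coding sequences from a FASTA file (plain or gzip).

    Entries violating the coding-sequence invariants are returned in the
    rejects list with a reason rather than silently dropped.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[CodingSequence] = []
    rejects: list[RejectedRecord] = []
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq).upper()
            if len(seq) == 0 or len(seq) % 3 != 0:
                rejects.append(RejectedRecord(rec.id, "length not multiple of 3"))
                continue
            bad = set(seq) - _VALID_BASES
            if bad:
                rejects.append(
                    RejectedRecord(rec.id, f"ambiguous or invalid bases: {sorted(bad)}")
                )
                continue
            records.append(CodingSequence(rec.id, seq))
    return records, rejects


def write_fasta(records: Iterable[CodingSequence], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.gene_id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _considered_codons(cds: CodingSequence, include_terminal_stop: bool) -> list[str]:
    codons = cds.codons
    if not include_terminal_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return codons


def gc_by_codon_position(
    cds: CodingSequence, include_terminal_stop: bool = False
) -> tuple[float, float, float]:
    """Proportion of G/C at codon positions 1, 2 and 3 (the wobble position).

    The terminal stop codon is excluded by default: GC3 is motivated by
    wobble-position decoding during elongation, which stop codons do not
    undergo.
    """
    codons = _considered_codons(cds, include_terminal_stop)
    if not codons:
        raise ValueError(f"{cds.gene_id}: no codons left after stop exclusion")
    n = len(codons)
    gc = [0, 0, 0]
    for codon in codons:
        for k in range(3):
            if codon[k] in "GC":
                gc[k] += 1
    return gc[0] / n, gc[1] / n, gc[2] / n


def relative_adaptiveness(
    counts: Mapping[str, float], pseudo_count: float = 0.5
) -> CodonUsageTable:
    """Build relative-adaptiveness weights w from codon counts.

    Within each synonymous family, w = (count + pseudo_count) / max of the
    family. The pseudo-count keeps w > 0 (hence CAI > 0) when a codon is
    unobserved in the reference set.
    """
    if pseudo_count < 0:
        raise ValueError("pseudo_count must be non-negative")
    missing = [c for c in SENSE_CODONS if c not in counts]
    if missing:
        raise ValueError(f"counts missing sense codons: {missing[:5]}...")
    negative = [c for c in SENSE_CODONS if counts[c] < 0]
    if negative:
        raise ValueError(f"negative counts for codons: {negative}")
    w: dict[str, float] = {}
    for codons in SYNONYMOUS_FAMILIES.values():
        adjusted = {c: counts[c] + pseudo_count for c in codons}
        top = max(adjusted.values())
        if top == 0:  # all-zero family with zero pseudo-count: flat weights
            w.update({c: 1.0 for c in codons})
        else:
            w.update({c: v / top for c, v in adjusted.items()})
    return CodonUsageTable(counts=dict(counts), w=w)


def cai(cds: CodingSequence, table: CodonUsageTable) -> float:
    """Codon adaptation index: geometric mean of w over informative codons.

    Stop codons and the single-codon amino acids Met (ATG) and Trp (TGG)
    are excluded, following the Sharp & Li convention. Accumulates in log
    space so long sequences do not underflow.
    """
    log_sum = 0.0
    n = 0
    for codon in cds.codons:
        if codon in STOP_CODONS:
            continue
        aa = CODON_TO_AA[codon]
        if aa in SINGLE_CODON_AAS:
            continue
        w = table.w.get(codon)
        if w is None:
            raise ValueError(f"no relative-adaptiveness weight for codon {codon}")
        if w <= 0:
            raise ValueError(f"non-positive weight for codon {codon}")
        log_sum += math.log(w)
        n += 1
    if n == 0:
        raise ValueError(f"{cds.gene_id}: no countable codons for CAI")
    return math.exp(log_sum / n)


def nte_score(
    cds: CodingSequence, table: Mapping[str, float], aggregation: str = "mean"
) -> float:
    """Per-transcript normalized translational efficiency.

    Aggregates per-codon nTE weights over sense codons (terminal stop
    excluded). Aggregation is the arithmetic mean by default; a geometric
    mean is available since the per-transcript rule is a convention rather
    than part of the score's definition.
    """
    codons = [c for c in cds.codons if c not in STOP_CODONS]
    if not codons:
        raise ValueError(f"{cds.gene_id}: no sense codons for nTE")
    values = []
    for codon in codons:
        if codon not in table:
            raise ValueError(f"nTE table missing codon {codon}")
        values.append(table[codon])
    if aggregation == "mean":
        return sum(values) / len(values)
    if aggregation == "geometric":
        if any(v <= 0 for v in values):
            raise ValueError("geometric nTE aggregation requires positive weights")
        return math.exp(sum(math.log(v) for v in values) / len(values))
    raise ValueError(f"unknown aggregation {aggregation!r}")


def polyproline_class(cds: CodingSequence, min_run: int = 4) -> bool:
    """True iff the transcript contains >= min_run consecutive proline codons."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    run = 0
    for codon in cds.codons:
        if codon in PROLINE_CODONS:
            run += 1
            if run >= min_run:
                return True
        else:
            run = 0
    return False


def read_codon_weights(path: str | Path) -> dict[str, float]:
    """Read a 2-column TSV (codon<TAB>value) into a codon->value map."""
    out: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            codon, value = line.split("\t")[:2]
            codon = codon.upper().replace("U", "T")
            if codon == "CODON":  # header
                continue
            out[codon] = float(value)
    return out


def feature_table(
    records: Iterable[CodingSequence],
    usage: CodonUsageTable,
    nte: Mapping[str, float] | None = None,
    min_polyproline_run: int = 4,
    include_terminal_stop: bool = False,
) -> pd.DataFrame:
    """Compute the full sequence-feature table for a set of coding sequences.

    Columns: gene_id, coding_length, gc1, gc2, gc3, cai, nte, polyproline.
    nte is NaN when no nTE table is supplied.
    """
    rows = []
    for rec in records:
        gc1, gc2, gc3 = gc_by_codon_position(rec, include_terminal_stop)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "coding_length": len(rec),
                "gc1": gc1,
                "gc2": gc2,
                "gc3": gc3,
                "cai": cai(rec, usage),
                "nte": nte_score(rec, nte) if nte is not None else float("nan"),
                "polyproline": polyproline_class(rec, min_polyproline_run),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "coding_length",
            "gc1",
            "gc2",
            "gc3",
            "cai",
            "nte",
            "polyproline",
        ],
    )
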