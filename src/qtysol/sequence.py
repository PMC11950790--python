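"""QTY sequence conversion and physicochemical characterization.

The QTY code replaces the hydrophobic residues that dominate transmembrane
(TM) helices with hydrophilic residues of near-identical side-chain shape:

    L -> Q,  I -> T,  V -> T,  F -> Y

Because glutamine, threonine and tyrosine are uncharged at physiological pH,
the substitution leaves the isoelectric point nearly unchanged and raises the
molecular weight only slightly, while removing most of the lipid-facing
hydrophobic surface.  This module applies the code to annotated sequences and
computes the standard per-protein characteristics: substitution percentages
(overall and TM-restricted), average molecular weight, and isoelectric point
under a Henderson-Hasselbalch charge model.

Sequence coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

__all__ = [
    "AMINO_ACIDS",
    "QTY_MAP",
    "TMSegment",
    "ProteinRecord",
    "QTYResult",
    "ResidueMassTable",
    "PkaTable",
    "NoTransmembraneAnnotationError",
    "SequenceParseError",
    "apply_qty_code",
    "variation_percentages",
    "molecular_weight",
    "free_amino_acid_mass",
    "isoelectric_point",
    "net_charge",
    "render_alignment",
    "read_fasta",
    "write_fasta",
    "read_segments_tsv",
    "write_segments_tsv",
    "parse_uniprot_transmem",
    "characteristics_table",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: The QTY substitution code. Q, T and Y are fixed points (the map applied to
#: its own image is the identity), which makes the conversion idempotent.
QTY_MAP: Mapping[str, str] = {"L": "Q", "I": "T", "V": "T", "F": "Y"}


class NoTransmembraneAnnotationError(ValueError):
    """Raised when TM-restricted conversion is requested without TM segments."""


class SequenceParseError(ValueError):
    """Raised for sequences containing non-canonical residue codes."""


@dataclass(frozen=True, order=True)
class TMSegment:
    """A transmembrane segment as a 1-based inclusive residue interval."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid TM segment ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class ProteinRecord:
    """An annotated protein sequence.

    Parameters
    ----------
    id : accession or name.
    sequence : one-letter residue string (canonical 20 codes only).
    tm_segments : sorted, non-overlapping transmembrane intervals,
        1-based inclusive.
    description : free text carried through to FASTA output.
    """

    id: str
    sequence: str
    tm_segments: tuple[TMSegment, ...] = ()
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceParseError(f"{self.id}: empty sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in AMINO_ACIDS:
                raise SequenceParseError(
                    f"{self.id}: non-canonical residue {aa!r} at position {i}"
                )
        segs = tuple(
            s if isinstance(s, TMSegment) else TMSegment(*s) for s in self.tm_segments
        )
        object.__setattr__(self, "tm_segments", segs)
        n = len(self.sequence)
        prev_end = 0
        for seg in segs:
            if seg.start <= prev_end:
                raise ValueError(f"{self.id}: TM segments overlap or are unsorted")
            if seg.end > n:
                raise ValueError(
                    f"{self.id}: TM segment ({seg.start}, {seg.end}) exceeds length {n}"
                )
            prev_end = seg.end

    def __len__(self) -> int:
        return len(self.sequence)

    def tm_positions(self) -> list[int]:
        """All residue positions (1-based) inside TM segments."""
        return [p for seg in self.tm_segments for p in range(seg.start, seg.end + 1)]

    def in_tm(self, position: int) -> bool:
        return any(position in seg for seg in self.tm_segments)


# Expasy-compatible average in-chain residue masses (Da): the mass each
# residue contributes to a polypeptide. A free amino acid weighs one water
# more; the per-protein MW adds a single water for the termini.
DEFAULT_RESIDUE_MASSES: Mapping[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153


@dataclass(frozen=True)
class ResidueMassTable:
    """Average residue masses (Da) used for molecular-weight computation."""

    masses: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RESIDUE_MASSES))
    water_mass: float = WATER_MASS

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.masses)
        if missing:
            raise ValueError(f"mass table missing residues: {sorted(missing)}")

    def residue_mass(self, code: str) -> float:
        return self.masses[code]

    def free_amino_acid_mass(self, code: str) -> float:
        """Mass of the free amino acid (residue + one water)."""
        return self.masses[code] + self.water_mass


# Bjellqvist/Expasy pKa values; the same set Expasy's Compute pI/MW and
# Biopython's IsoelectricPoint use.
DEFAULT_PKA: Mapping[str, float] = {
    "Nterm": 7.5, "Cterm": 3.55,
    "D": 4.05, "E": 4.45, "H": 5.98, "C": 9.0, "Y": 10.0, "K": 10.0, "R": 12.0,
}
_POSITIVE_GROUPS = ("Nterm", "K", "R", "H")
_NEGATIVE_GROUPS = ("Cterm", "D", "E", "C", "Y")


@dataclass(frozen=True)
class PkaTable:
    """pKa values for the termini and the ionizable side chains."""

    pka: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_PKA))

    def __post_init__(self) -> None:
        for group, value in self.pka.items():
            if not (0.0 < value < 14.0):
                raise ValueError(f"pKa for {group} out of (0, 14): {value}")
        missing = set(DEFAULT_PKA) - set(self.pka)
        if missing:
            raise ValueError(f"pKa table missing groups: {sorted(missing)}")


@dataclass
class QTYResult:
    """Outcome of one QTY conversion, with sequence characteristics."""

    native: ProteinRecord
    analog_sequence: str
    substitutions: list[tuple[int, str, str]]
    overall_variation_pct: float
    tm_variation_pct: float | None
    native_mw: float
    analog_mw: float
    native_pi: float
    analog_pi: float

    @property
    def analog_record(self) -> ProteinRecord:
        return ProteinRecord(
            id=f"{self.native.id}_QTY",
            sequence=self.analog_sequence,
            tm_segments=self.native.tm_segments,
            description=(self.native.description + " QTY analog").strip(),
        )


def _validate_sequence(sequence: str, name: str = "sequence") -> None:
    if not sequence:
        raise SequenceParseError(f"{name} is empty")
    for i, aa in enumerate(sequence, start=1):
        if aa not in AMINO_ACIDS:
            raise SequenceParseError(
                f"{name}: non-canonical residue {aa!r} at position {i}"
            )


def molecular_weight(sequence: str, table: ResidueMassTable | None = None) -> float:
    """Average molecular weight in Da: sum of residue masses plus one water."""
    table = table or ResidueMassTable()
    _validate_sequence(sequence)
    return sum(table.residue_mass(aa) for aa in sequence) + table.water_mass


def free_amino_acid_mass(code: str, table: ResidueMassTable | None = None) -> float:
    table = table or ResidueMassTable()
    return table.free_amino_acid_mass(code)


def net_charge(sequence: str, ph: float, pka: PkaTable | None = None) -> float:
    """Net Henderson-Hasselbalch charge of the peptide at the given pH.

    Termini plus ionizable side chains D, E, H, C, Y, K, R. Monotone
    non-increasing in pH, so the isoelectric point is the unique root.
    """
    pka = pka or PkaTable()
    counts = {g: sequence.count(g) for g in ("D", "E", "H", "C", "Y", "K", "R")}
    counts["Nterm"] = 1
    counts["Cterm"] = 1
    charge = 0.0
    for group in _POSITIVE_GROUPS:
        charge += counts[group] / (1.0 + 10.0 ** (ph - pka.pka[group]))
    for group in _NEGATIVE_GROUPS:
        charge -= counts[group] / (1.0 + 10.0 ** (pka.pka[group] - ph))
    return charge


def isoelectric_point(
    sequence: str, pka: PkaTable | None = None, tol: float = 1e-3
) -> float:
    """pH at which the net charge crosses zero, by bisection on [0, 14]."""
    _validate_sequence(sequence)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def apply_qty_code(
    record: ProteinRecord,
    scope: Literal["tm_only", "whole_sequence"] = "tm_only",
    mass_table: ResidueMassTable | None = None,
    pka_table: PkaTable | None = None,
) -> QTYResult:
    """Apply the QTY substitution code to an annotated sequence.

    In the default ``tm_only`` scope only residues inside annotated TM
    segments are substituted; ``whole_sequence`` converts every L/I/V/F.

    Raises
    ------
    NoTransmembraneAnnotationError
        if ``scope == "tm_only"`` and the record carries no TM segments —
        an unannotated record would otherwise silently convert nothing.
    """
    if scope not in ("tm_only", "whole_sequence"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "tm_only" and not record.tm_segments:
        raise NoTransmembraneAnnotationError(
            f"{record.id}: no TM segments annotated; "
            "supply segments or use scope='whole_sequence'"
        )

    analog = list(record.sequence)
    substitutions: list[tuple[int, str, str]] = []
    for pos in range(1, len(record.sequence) + 1):
        if scope == "tm_only" and not record.in_tm(pos):
            continue
        aa = record.sequence[pos - 1]
        if aa in QTY_MAP:
            analog[pos - 1] = QTY_MAP[aa]
            substitutions.append((pos, aa, QTY_MAP[aa]))
    analog_sequence = "".join(analog)

    n_tm = sum(len(seg) for seg in record.tm_segments)
    n_sub_tm = sum(1 for pos, _, _ in substitutions if record.in_tm(pos))
    overall_pct = round(100.0 * len(substitutions) / len(record.sequence), 2)
    tm_pct = round(100.0 * n_sub_tm / n_tm, 2) if n_tm else None

    return QTYResult(
        native=record,
        analog_sequence=analog_sequence,
        substitutions=substitutions,
        overall_variation_pct=overall_pct,
        tm_variation_pct=tm_pct,
        native_mw=molecular_weight(record.sequence, mass_table),
        analog_mw=molecular_weight(analog_sequence, mass_table),
        native_pi=isoelectric_point(record.sequence, pka_table),
        analog_pi=isoelectric_point(analog_sequence, pka_table),
    )


def variation_percentages(result: QTYResult) -> tuple[float, float]:
    """(overall %, TM %) substitution percentages, rounded to 2 decimals.

    Raises ValueError if the record has no TM residues: a TM percentage of
    an empty set is undefined, not zero.
    """
    if result.tm_variation_pct is None:
        raise ValueError(
            f"{result.native.id}: TM variation undefined (no TM residues)"
        )
    return result.overall_variation_pct, result.tm_variation_pct


def render_alignment(
    native: ProteinRecord,
    analog_sequence: str,
    width: int = 60,
    annotate_tm: bool = True,
) -> str:
    """Pairwise alignment text in three-line blocks.

    The marker line carries ``|`` where native and analog agree and ``*``
    where they differ. With ``annotate_tm`` an extra line marks TM columns
    with ``H`` (helix).
    """
    if len(native.sequence) != len(analog_sequence):
        raise ValueError(
            f"length mismatch: native {len(native.sequence)}, "
            f"analog {len(analog_sequence)}"
        )
    seq_a, seq_b = native.sequence, analog_sequence
    markers = "".join("|" if a == b else "*" for a, b in zip(seq_a, seq_b))
    tm_line = "".join("H" if native.in_tm(i + 1) else " " for i in range(len(seq_a)))

    blocks: list[str] = []
    for off in range(0, len(seq_a), width):
        end = min(off + width, len(seq_a))
        lines = []
        if annotate_tm:
            lines.append("TM      " + tm_line[off:end])
        lines.append(f"{off + 1:<8}" + seq_a[off:end])
        lines.append(" " * 8 + markers[off:end])
        lines.append(f"{off + 1:<8}" + seq_b[off:end])
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


# ---------------------------------------------------------------------------
# File formats: FASTA via Biopython, segment tables as plain TSV
# (id <TAB> start <TAB> end, 1-based inclusive).

def read_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTA into (id, sequence, description) tuples."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append((rec.id, str(rec.seq).upper(), desc))
    return out


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for off in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[off:off + width] + "\n")


def read_segments_tsv(path: str | Path) -> dict[str, list[TMSegment]]:
    """Read a segment table: ``id<TAB>start<TAB>end``, 1-based inclusive."""
    segments: dict[str, list[TMSegment]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            name, start, end = parts
            if name == "id" and lineno == 1:
                continue
            segments.setdefault(name, []).append(TMSegment(int(start), int(end)))
    for segs in segments.values():
        segs.sort()
    return segments


def write_segments_tsv(segments: Mapping[str, Sequence[TMSegment]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tstart\tend\n")
        for name, segs in segments.items():
            for seg in segs:
                fh.write(f"{name}\t{seg.start}\t{seg.end}\n")


def parse_uniprot_transmem(text: str) -> list[TMSegment]:
    """Extract TRANSMEM intervals from UniProt flat-file feature lines.

    Accepts both the current ``FT   TRANSMEM        35..58`` layout and the
    legacy two-column ``FT   TRANSMEM   35   58`` layout.
    """
    segments: list[TMSegment] = []
    for line in text.splitlines():
        if not line.startswith("FT") or "TRANSMEM" not in line:
            continue
        rest = line.split("TRANSMEM", 1)[1].strip()
        if ".." in rest:
            start_s, end_s = rest.split("..", 1)
        else:
            fields = rest.split()
            if len(fields) < 2:
                continue
            start_s, end_s = fields[0], fields[1]
        try:
            segments.append(TMSegment(int(start_s.strip()), int(end_s.strip())))
        except ValueError:
            continue
    return sorted(segments)


def characteristics_table(results: Iterable[QTYResult]):
    """Per-protein characteristics as a DataFrame (one row per subunit).

    Columns mirror the standard report: pI and MW for native and analog,
    overall and TM variation percentages.
    """
    import pandas as pd

    rows = []
    for res in results:
        rows.append({
            "id": res.native.id,
            "pI": round(res.native_pi, 2),
            "pI_QTY": round(res.analog_pi, 2),
            "MW": round(res.native_mw, 2),
            "MW_QTY": round(res.analog_mw, 2),
            "total_variation_pct": res.overall_variation_pct,
            "tm_variation_pct": res.tm_variation_pct,
        })
    return pd.DataFrame(rows)
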