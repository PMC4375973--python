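"""Reading, pairing, filtering and summarising protein chemical shifts.

Experimental and predicted chemical shifts arrive as flat tables keyed by
(residue index, nucleus).  The six nucleus classes handled are the backbone
and near-backbone nuclei commonly covered by structure-based shift
predictors: Cα, Cβ, carbonyl C, amide N, amide H and Hα.  Each class has its
own prediction-error scale, so downstream error models consume a per-class
summary: the deviations Δδ = δ_pred − δ_exp, their count n_j and the misfit
χ²_j = Σ Δδ².

Two plain-text input formats are supported: a four-column TSV dialect and a
minimal read-only subset of the NMR-STAR v3 ``_Atom_chem_shift`` loop (the
format BMRB chemical-shift depositions use).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

logger = logging.getLogger(__name__)

#: The six nucleus classes with distinct error scales.
NUCLEI: Tuple[str, ...] = ("CA", "CB", "C", "N", "H", "HA")

AMINO_ACIDS: Tuple[str, ...] = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

TSV_HEADER = ("residue_index", "residue_type", "nucleus", "shift_ppm")

# NMR-STAR atom names accepted by the minimal reader, mapped onto the six
# classes. HA2 stands in for Hα on glycine; HA3 (the second glycine Hα) and
# every other atom are skipped.
_STAR_ATOM_MAP = {
    "CA": "CA", "CB": "CB", "C": "C", "N": "N",
    "H": "H", "HA": "HA", "HA2": "HA",
}


class ShiftParseError(ValueError):
    """A row of an input file could not be parsed."""


class IntegrityError(ValueError):
    """Duplicate (residue_index, nucleus) keys in one table."""


class EmptyOverlapError(ValueError):
    """No (residue_index, nucleus) key is shared by the two tables."""


class SummaryOnlyError(TypeError):
    """An operation needing individual deviations got a summary-only input."""


@dataclass(frozen=True)
class ShiftRecord:
    """One nucleus's chemical shift with its residue identity.

    ``shift`` is in ppm and must be finite; ``residue_index`` follows the
    deposited (1-based) numbering.
    """

    residue_index: int
    residue_type: str
    nucleus: str
    shift: float

    def __post_init__(self) -> None:
        if self.residue_index < 1:
            raise ValueError(f"residue_index must be >= 1, got {self.residue_index}")
        if self.nucleus not in NUCLEI:
            raise ValueError(f"unknown nucleus class {self.nucleus!r}")
        if not math.isfinite(self.shift):
            raise ValueError(f"shift must be finite, got {self.shift!r}")

    @property
    def key(self) -> Tuple[int, str]:
        return (self.residue_index, self.nucleus)


@dataclass
class ShiftTable:
    """A set of shift records with unique (residue_index, nucleus) keys."""

    records: List[ShiftRecord]
    label: str = ""
    #: rows skipped during parsing (unknown nuclei); metadata, not identity.
    n_skipped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            if rec.key in seen:
                raise IntegrityError(
                    f"duplicate record for residue {rec.residue_index} "
                    f"nucleus {rec.nucleus} in table {self.label!r}"
                )
            seen.add(rec.key)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ShiftRecord]:
        return iter(self.records)

    def by_key(self) -> Dict[Tuple[int, str], ShiftRecord]:
        return {rec.key: rec for rec in self.records}


@dataclass
class DeviationSummary:
    """Per-class deviations Δδ = δ_pred − δ_exp with counts and χ².

    All six classes are always present; empty classes carry ``n = 0``.
    A summary-only instance (built from printed n/χ² pairs rather than
    individual shifts) supports the Gaussian-family models, which depend on
    the data only through χ², but is rejected by Cauchy operations, whose
    likelihood does not reduce to χ².
    """

    deviations: Dict[str, np.ndarray]
    counts: Dict[str, int]
    chi_squares: Dict[str, float]
    summary_only: bool = False

    def __post_init__(self) -> None:
        for j in NUCLEI:
            self.deviations.setdefault(j, np.empty(0))
            self.counts.setdefault(j, 0)
            self.chi_squares.setdefault(j, 0.0)
        if not self.summary_only:
            for j in NUCLEI:
                if self.counts[j] != len(self.deviations[j]):
                    raise ValueError(f"count mismatch for class {j}")

    @classmethod
    def from_deviations(cls, per_class: Mapping[str, Sequence[float]]) -> "DeviationSummary":
        devs = {j: np.asarray(per_class.get(j, ()), dtype=float) for j in NUCLEI}
        counts = {j: int(devs[j].size) for j in NUCLEI}
        # compensated summation: n_j can reach thousands in stress tests
        chi = {j: float(math.fsum(d * d for d in devs[j])) for j in NUCLEI}
        return cls(deviations=devs, counts=counts, chi_squares=chi)

    def n(self, nucleus: str) -> int:
        return self.counts[nucleus]

    def chi_square(self, nucleus: str) -> float:
        return self.chi_squares[nucleus]

    def classes_with_data(self) -> List[str]:
        return [j for j in NUCLEI if self.counts[j] > 0]

    def total_n(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_shift_table(
    path: Union[str, Path], format: str = "tsv", label: str = ""
) -> ShiftTable:
    """Read a shift table from ``path``.

    ``format`` is ``"tsv"`` (the package's four-column dialect) or
    ``"nmrstar"`` (minimal ``_Atom_chem_shift`` loop reader).  Rows naming a
    nucleus outside the six classes are skipped and counted on the returned
    table's ``n_skipped``; duplicate keys raise :class:`IntegrityError`.
    """
    path = Path(path)
    if format == "tsv":
        records, skipped = _parse_tsv(path)
    elif format == "nmrstar":
        records, skipped = _parse_nmrstar(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if skipped:
        logger.info("%s: skipped %d rows with unmapped nuclei", path, skipped)
    return ShiftTable(records=records, label=label or path.name, n_skipped=skipped)


def write_shift_table(table: ShiftTable, path: Union[str, Path]) -> None:
    """Write ``table`` in the TSV dialect (round-trips bit-exactly)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("\t".join(TSV_HEADER) + "\n")
        for rec in table.records:
            fh.write(
                f"{rec.residue_index}\t{rec.residue_type}\t{rec.nucleus}\t{rec.shift!r}\n"
            )


def _parse_tsv(path: Path) -> Tuple[List[ShiftRecord], int]:
    records: List[ShiftRecord] = []
    skipped = 0
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if not header_seen:
                header_seen = True
                if tuple(fields) == TSV_HEADER:
                    continue  # header row, fall through to parse otherwise
            if len(fields) != 4:
                raise ShiftParseError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            idx_s, rtype, nucleus, shift_s = fields
            try:
                idx = int(idx_s)
                shift = float(shift_s)
            except ValueError as exc:
                raise ShiftParseError(f"{path}:{lineno}: {exc}") from None
            nucleus = nucleus.upper()
            if nucleus not in NUCLEI:
                skipped += 1
                continue
            try:
                records.append(
                    ShiftRecord(idx, rtype.upper(), nucleus, shift)
                )
            except ValueError as exc:
                raise ShiftParseError(f"{path}:{lineno}: {exc}") from None
    return records, skipped


def _parse_nmrstar(path: Path) -> Tuple[List[ShiftRecord], int]:
    """Minimal reader for the NMR-STAR v3 ``_Atom_chem_shift`` loop.

    Only four columns are consumed: the sequence ID (``Seq_ID`` or
    ``Comp_index_ID``), ``Comp_ID``, ``Atom_ID`` and ``Val``.  Atom IDs are
    mapped per :data:`_STAR_ATOM_MAP`; everything else (including HA3 and
    other would-be duplicates) is skipped and counted.
    """
    lines = path.read_text(encoding="utf-8").splitlines()
    records: List[ShiftRecord] = []
    seen: set = set()
    skipped = 0
    i = 0
    while i < len(lines):
        if lines[i].strip() != "loop_":
            i += 1
            continue
        i += 1
        tags: List[str] = []
        while i < len(lines) and lines[i].strip().startswith("_"):
            tags.append(lines[i].strip())
            i += 1
        if not any(t.startswith("_Atom_chem_shift.") for t in tags):
            continue
        names = [t.split(".", 1)[1] for t in tags]
        try:
            seq_col = names.index("Seq_ID") if "Seq_ID" in names else names.index("Comp_index_ID")
            comp_col = names.index("Comp_ID")
            atom_col = names.index("Atom_ID")
            val_col = names.index("Val")
        except ValueError:
            raise ShiftParseError(f"{path}: chemical-shift loop lacks a required column")
        while i < len(lines):
            line = lines[i].strip()
            i += 1
            if not line or line.startswith("#"):
                continue
            if line == "stop_":
                break
            fields = line.split()
            if len(fields) <= max(seq_col, comp_col, atom_col, val_col):
                raise ShiftParseError(f"{path}:{i}: truncated loop row")
            nucleus = _STAR_ATOM_MAP.get(fields[atom_col].upper())
            if nucleus is None:
                skipped += 1
                continue
            try:
                idx = int(fields[seq_col])
                shift = float(fields[val_col])
            except ValueError as exc:
                raise ShiftParseError(f"{path}:{i}: {exc}") from None
            key = (idx, nucleus)
            if key in seen:
                skipped += 1
                continue
            seen.add(key)
            records.append(ShiftRecord(idx, fields[comp_col].upper(), nucleus, shift))
    return records, skipped


# ---------------------------------------------------------------------------
# Pairing and summarising
# ---------------------------------------------------------------------------

def compute_deviations(
    experimental: ShiftTable,
    predicted: ShiftTable,
    exclude_ile_cb: bool = True,
) -> DeviationSummary:
    """Pair the two tables and summarise Δδ = δ_pred − δ_exp per class.

    Pairing is by exact (residue_index, nucleus) key; records present in only
    one table are ignored (and counted in a log line).  Residue-type
    disagreements between matched records are a warning, not an error —
    deposited files often disagree on tags.

    With ``exclude_ile_cb`` (the default) every matched isoleucine Cβ pair is
    dropped before summarising: structure-based predictors whose side-chain
    geometry is frozen mispredict Ile Cβ by several ppm, so those deviations
    measure a modelling artefact rather than the error law being calibrated.
    """
    if len(experimental) == 0 or len(predicted) == 0:
        raise EmptyOverlapError("both tables must be nonempty")
    exp_by_key = experimental.by_key()
    per_class: Dict[str, List[float]] = {j: [] for j in NUCLEI}
    n_matched = 0
    n_type_mismatch = 0
    for pred_rec in predicted:
        exp_rec = exp_by_key.get(pred_rec.key)
        if exp_rec is None:
            continue
        if exp_rec.residue_type != pred_rec.residue_type:
            n_type_mismatch += 1
        if (
            exclude_ile_cb
            and pred_rec.nucleus == "CB"
            and (pred_rec.residue_type == "ILE" or exp_rec.residue_type == "ILE")
        ):
            continue
        per_class[pred_rec.nucleus].append(pred_rec.shift - exp_rec.shift)
        n_matched += 1
    if n_matched == 0:
        raise EmptyOverlapError(
            "the experimental and predicted tables share no usable "
            "(residue_index, nucleus) key"
        )
    if n_type_mismatch:
        logger.warning(
            "%d matched records disagree on residue_type between tables",
            n_type_mismatch,
        )
    n_unmatched = len(predicted) + len(experimental) - 2 * n_matched
    if n_unmatched:
        logger.info("%d records present in only one table were ignored", n_unmatched)
    return DeviationSummary.from_deviations(per_class)


def summary_from_scalars(
    per_class: Mapping[str, Tuple[int, float]]
) -> DeviationSummary:
    """Build a summary-only :class:`DeviationSummary` from (n, χ²) pairs.

    This supports scenarios where only per-class counts and χ² values are
    known (e.g. published summaries).  Valid for Gaussian-family models only;
    Cauchy operations reject the result because their likelihood needs the
    individual deviations.
    """
    counts: Dict[str, int] = {}
    chi: Dict[str, float] = {}
    for j, (n, chi2) in per_class.items():
        if j not in NUCLEI:
            raise ValueError(f"unknown nucleus class {j!r}")
        if n < 0 or chi2 < 0:
            raise ValueError(f"negative n or chi_square for class {j}")
        if n == 0 and chi2 > 0:
            raise ValueError(f"class {j}: chi_square > 0 requires n >= 1")
        counts[j] = int(n)
        chi[j] = float(chi2)
    return DeviationSummary(
        deviations={j: np.empty(0) for j in NUCLEI},
        counts=counts,
        chi_squares=chi,
        summary_only=True,
    )
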