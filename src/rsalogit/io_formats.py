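"""Readers and writers for every external format the pipeline touches.

The pipeline consumes four kinds of input: query chain sequences (FASTA),
per-chain homolog alignments (a BLAST-style tabular dialect that carries bit
scores and the pairwise aligned query/subject strings), per-residue relative
solvent accessibility (NACCESS ``.rsa`` files or a plain residue CSV), and
optional per-residue disorder propensities (LGDP) as a CSV column.  Fitted
models round-trip through a JSON schema so prediction-only runs need no
refitting.

Alignment dialect
-----------------
Tab-separated columns ``qseqid  sseqid  bitscore  qstart  qseq  sseq`` (an
optional header line is detected by a non-numeric ``bitscore`` field).  This
is exactly what a single BLASTp invocation emits with
``-outfmt "6 qseqid sseqid bitscore qstart qseq sseq"``.

Conventions
-----------
All residue positions are 1-based and inclusive.  Missing numeric fields are
explicit missing values (``None`` in records, ``NaN`` in frames), never zero.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("rsalogit")

# --------------------------------------------------------------------------
# Shared constants
# --------------------------------------------------------------------------

#: The 20 standard amino acids, one-letter codes, alphabetical.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
STANDARD_AA_SET = frozenset(STANDARD_AA)

#: Placeholder for an undefined residue in a query FASTA record.
UNDEFINED_AA = "X"

#: Alignment gap character.
GAP = "-"

#: Distinguished level used for the adjacent-neighbor factor at chain termini.
BOUNDARY = "*"

AA_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
AA_THREE_TO_ONE = {v: k for k, v in AA_ONE_TO_THREE.items()}

#: Strongly hydrophobic residues (the FSHP set).
STRONGLY_HYDROPHOBIC = frozenset("VLIFYMW")

#: Small residues (the FSR set).
SMALL_RESIDUES = frozenset("GA")

MODEL_JSON_VERSION = 1

SINGLE_CHAIN = "single_chain"
COMPLEX = "complex"

OPTIMUM = "optimum"
NON_OPTIMUM = "non_optimum"


# --------------------------------------------------------------------------
# Exceptions (shared by the whole package)
# --------------------------------------------------------------------------

class PipelineError(Exception):
    """Base class for all rsalogit errors."""


class ParseError(PipelineError):
    """An input file violates its format or an invariant of its contents."""


class ModelError(PipelineError):
    """Model specification, fitting or prediction failed."""


class EvaluationError(PipelineError):
    """Evaluation could not be carried out (empty strata, missing fits)."""


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainSequence:
    """A query protein chain: an ordered string of one-letter residue codes.

    ``chain_id`` is typically a PDB id plus chain letter (e.g. ``"1axna"``).
    Residues are uppercase; any letter outside the 20 standard codes is the
    placeholder 'X'.  Positions are implicit: residue i sits at 1-based
    position i.
    """

    chain_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.chain_id:
            raise ParseError("ChainSequence requires a non-empty chain_id")
        if not self.sequence:
            raise ParseError(f"chain {self.chain_id!r}: empty sequence")
        bad = set(self.sequence) - STANDARD_AA_SET - {UNDEFINED_AA}
        if bad:
            raise ParseError(
                f"chain {self.chain_id!r}: invalid residue codes {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue code at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise IndexError(
                f"position {position} out of range 1..{len(self.sequence)} "
                f"for chain {self.chain_id!r}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class PairwiseHit:
    """One pairwise local alignment of a homolog against the query chain.

    ``aligned_query``/``aligned_subject`` are the gapped alignment strings of
    equal length; ``query_start`` is the 1-based query position of the first
    aligned (non-gap) query residue.
    """

    query_id: str
    subject_id: str
    bit_score: float
    query_start: int
    aligned_query: str
    aligned_subject: str

    def __post_init__(self) -> None:
        if len(self.aligned_query) != len(self.aligned_subject):
            raise ParseError(
                f"hit {self.query_id!r}/{self.subject_id!r}: aligned strings "
                f"differ in length ({len(self.aligned_query)} vs "
                f"{len(self.aligned_subject)})"
            )
        if self.bit_score < 0:
            raise ParseError(
                f"hit {self.query_id!r}/{self.subject_id!r}: negative bit "
                f"score {self.bit_score}"
            )
        if self.query_start < 1:
            raise ParseError(
                f"hit {self.query_id!r}/{self.subject_id!r}: query_start "
                f"must be >= 1, got {self.query_start}"
            )

    @property
    def query_span(self) -> int:
        """Number of query residues covered (non-gap columns of the query)."""
        return sum(1 for c in self.aligned_query if c != GAP)


@dataclass
class RsaTable:
    """Per-residue relative solvent accessibility (percent) for one chain.

    ``context`` records whether the accessibilities were computed on the
    isolated chain or on the full biological-unit complex; the difference
    between the two flags likely interfacial residues.  Relative values can
    slightly exceed 100 for extended conformations and are accepted.
    """

    chain_id: str
    values: dict[int, float]
    context: str = SINGLE_CHAIN
    provenance: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.context not in (SINGLE_CHAIN, COMPLEX):
            raise ParseError(f"unknown RSA context {self.context!r}")
        for pos, val in self.values.items():
            if val < 0:
                raise ParseError(
                    f"chain {self.chain_id!r} position {pos}: negative RSA "
                    f"{val}"
                )

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class ResidueRecord:
    """One residue's descriptors, label and provenance.

    Quantitative descriptors (``e20``, ``e6``, ``fshp``, ``fsr``, ``lgdp``)
    and the label are ``None`` when missing; records missing a descriptor
    required by the active model are excluded from that model's fit and
    evaluation only.
    """

    chain_id: str
    position: int
    aa: str | None = None
    e20: float | None = None
    e6: float | None = None
    fshp: float | None = None
    fsr: float | None = None
    lgdp: float | None = None
    aqn_prev: str | None = None
    aqn_next: str | None = None
    n_hits: int | None = None
    n_aligned: int | None = None
    homology_status: str | None = None
    rsa: float | None = None
    rsa_complex: float | None = None
    label: int | None = None
    oligomer: bool | None = None
    interfacial: bool | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ParseError(
                f"{self.chain_id}:{self.position}: label must be 0/1, got "
                f"{self.label!r}"
            )
        if self.lgdp is not None and not 0.0 <= self.lgdp <= 1.0:
            raise ParseError(
                f"{self.chain_id}:{self.position}: LGDP {self.lgdp} outside "
                f"[0, 1]"
            )


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ChainSequence]:
    """Read query chains from a FASTA file.

    Letters are uppercased; any letter outside the 20 standard codes is
    mapped to 'X' with a logged warning.  Duplicate record ids, zero-length
    records and empty files are errors.
    """
    path = Path(path)
    chains: list[ChainSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise ParseError(f"{path}: zero-length FASTA record {rec.id!r}")
        cleaned = []
        n_mapped = 0
        for letter in seq:
            if letter in STANDARD_AA_SET or letter == UNDEFINED_AA:
                cleaned.append(letter)
            else:
                cleaned.append(UNDEFINED_AA)
                n_mapped += 1
        if n_mapped:
            logger.warning(
                "%s: chain %s: %d non-standard residue letter(s) mapped to X",
                path, rec.id, n_mapped,
            )
        chains.append(ChainSequence(chain_id=rec.id, sequence="".join(cleaned)))
    if not chains:
        raise ParseError(f"{path}: no FASTA records found")
    return chains


def write_fasta(chains: Iterable[ChainSequence], path: str | Path) -> None:
    """Write chains as plain FASTA (60-column wrap)."""
    with open(path, "w") as fh:
        for chain in chains:
            fh.write(f">{chain.chain_id}\n")
            seq = chain.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


# --------------------------------------------------------------------------
# Alignment table (BLAST-style tabular dialect)
# --------------------------------------------------------------------------

_ALIGNMENT_COLUMNS = ("qseqid", "sseqid", "bitscore", "qstart", "qseq", "sseq")


def read_alignment_table(path: str | Path) -> list[PairwiseHit]:
    """Read pairwise hits from the tab-separated alignment dialect.

    Columns: qseqid, sseqid, bitscore, qstart, qseq, sseq.  A header line is
    optional and detected by a non-numeric bitscore field.  Trailing
    whitespace is ignored; ragged lines, unequal aligned lengths and negative
    bit scores are errors.
    """
    path = Path(path)
    hits: list[PairwiseHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != len(_ALIGNMENT_COLUMNS):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(_ALIGNMENT_COLUMNS)} "
                    f"tab-separated fields, got {len(fields)}"
                )
            qseqid, sseqid, bitscore_s, qstart_s, qseq, sseq = fields
            if lineno == 1:
                try:
                    float(bitscore_s)
                except ValueError:
                    continue  # header line
            try:
                bit_score = float(bitscore_s)
                qstart = int(qstart_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            try:
                hits.append(
                    PairwiseHit(
                        query_id=qseqid,
                        subject_id=sseqid,
                        bit_score=bit_score,
                        query_start=qstart,
                        aligned_query=qseq.upper(),
                        aligned_subject=sseq.upper(),
                    )
                )
            except ParseError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_alignment_table(
    hits: Iterable[PairwiseHit], path: str | Path, header: bool = True
) -> None:
    """Write hits in the tab-separated alignment dialect."""
    with open(path, "w") as fh:
        if header:
            fh.write("\t".join(_ALIGNMENT_COLUMNS) + "\n")
        for hit in hits:
            fh.write(
                f"{hit.query_id}\t{hit.subject_id}\t{hit.bit_score:g}\t"
                f"{hit.query_start}\t{hit.aligned_query}\t"
                f"{hit.aligned_subject}\n"
            )


# --------------------------------------------------------------------------
# NACCESS .rsa
# --------------------------------------------------------------------------

def read_naccess_rsa(path: str | Path, context: str = SINGLE_CHAIN) -> RsaTable:
    """Read a NACCESS ``.rsa`` file into an :class:`RsaTable`.

    Only ``RES`` lines are used.  Each carries residue name, chain, residue
    number (with optional insertion code) and then pairs of
    absolute/relative accessibilities; the *relative all-atoms* column — the
    second numeric field after the residue number — is taken.  Positions are
    assigned sequentially (1-based) in file order; PDB numbering and
    insertion codes are kept as provenance.
    """
    path = Path(path)
    values: dict[int, float] = {}
    provenance: dict[int, str] = {}
    chain_id = ""
    pos = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.startswith("RES"):
                continue
            tokens = raw.split()
            if len(tokens) < 5:
                raise ParseError(f"{path}:{lineno}: truncated RES line")
            resname = tokens[1]
            # Chain identifier may be absent (blank chain in the PDB); it is
            # present when the token after the residue name is non-numeric.
            if _is_number(tokens[2]):
                chain, resnum, numeric = "", tokens[2], tokens[3:]
            else:
                chain, resnum, numeric = tokens[2], tokens[3], tokens[4:]
            if len(numeric) < 2:
                raise ParseError(
                    f"{path}:{lineno}: RES line lacks accessibility columns"
                )
            try:
                rel_all_atoms = float(numeric[1])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: unparseable accessibility field "
                    f"{numeric[1]!r}"
                ) from exc
            pos += 1
            values[pos] = rel_all_atoms
            provenance[pos] = f"{resname} {chain}{resnum}"
            if chain and not chain_id:
                chain_id = chain
    if not values:
        raise ParseError(f"{path}: no RES lines found")
    return RsaTable(
        chain_id=chain_id or path.stem,
        values=values,
        context=context,
        provenance=provenance,
    )


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def write_naccess_rsa(
    table: RsaTable,
    residues: str,
    path: str | Path,
    chain_letter: str = "A",
) -> None:
    """Write an RsaTable as a synthetic NACCESS-style ``.rsa`` file.

    ``residues`` supplies one-letter codes in position order (for the RES
    residue-name column).  Absolute columns are filled with placeholder
    values proportional to the relative ones; only the relative all-atoms
    column is meaningful, matching what :func:`read_naccess_rsa` consumes.
    """
    with open(path, "w") as fh:
        fh.write("REM  Relative accessibilites read from external file\n")
        fh.write(
            "REM RES _ NUM      All-atoms   Total-Side   Main-Chain"
            "   Non-polar    All polar\n"
        )
        fh.write(
            "REM                ABS   REL    ABS   REL    ABS   REL"
            "    ABS   REL    ABS   REL\n"
        )
        for pos in sorted(table.values):
            rel = table.values[pos]
            aa = residues[pos - 1] if pos - 1 < len(residues) else "A"
            res3 = AA_ONE_TO_THREE.get(aa, "ALA")
            abs_area = rel * 1.6  # placeholder absolute area
            fh.write(
                f"RES {res3} {chain_letter}{pos:4d}   "
                f"{abs_area:6.2f}{rel:6.1f}  "
                f"{abs_area:6.2f}{rel:6.1f}  "
                f"{abs_area:6.2f}{rel:6.1f}  "
                f"{abs_area:6.2f}{rel:6.1f}  "
                f"{abs_area:6.2f}{rel:6.1f}\n"
            )


# --------------------------------------------------------------------------
# Residue CSV
# --------------------------------------------------------------------------

#: Columns accepted in a residue CSV (header-defined; any subset beyond the
#: two key columns).  ``nk`` is the per-position count of aligned subject
#: residues.
RESIDUE_CSV_COLUMNS = (
    "chain_id", "position", "aa", "e20", "e6", "fshp", "fsr", "lgdp",
    "aqn_prev", "aqn_next", "n_hits", "nk", "homology_status",
    "rsa", "rsa_complex", "label", "oligomer", "interfacial",
)

_NUMERIC_CSV_COLUMNS = {
    "e20", "e6", "fshp", "fsr", "lgdp", "rsa", "rsa_complex",
}
_INT_CSV_COLUMNS = {"position", "n_hits", "nk", "label"}
_BOOL_CSV_COLUMNS = {"oligomer", "interfacial"}

_CSV_TO_FIELD = {"nk": "n_aligned"}
_FIELD_TO_CSV = {"n_aligned": "nk"}


def read_residue_csv(path: str | Path) -> list[ResidueRecord]:
    """Read residue records from a header-defined CSV.

    Any subset of :data:`RESIDUE_CSV_COLUMNS` is accepted provided
    ``chain_id`` and ``position`` are present.  Absent fields and ``NA`` /
    empty cells become missing values.  Unknown column names and non-numeric
    entries in numeric columns are errors.  Lines starting with ``#`` are
    metadata and skipped.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", dtype="object")
    except pd.errors.EmptyDataError as exc:
        raise ParseError(f"{path}: empty residue CSV") from exc
    unknown = set(df.columns) - set(RESIDUE_CSV_COLUMNS)
    if unknown:
        raise ParseError(f"{path}: unknown column name(s) {sorted(unknown)}")
    for required in ("chain_id", "position"):
        if required not in df.columns:
            raise ParseError(f"{path}: missing required column {required!r}")
    records: list[ResidueRecord] = []
    for idx, row in df.iterrows():
        kwargs: dict = {}
        for col in df.columns:
            cell = row[col]
            field_name = _CSV_TO_FIELD.get(col, col)
            if pd.isna(cell) or (isinstance(cell, str) and cell.strip() in ("", "NA", "NaN")):
                continue
            try:
                if col in _NUMERIC_CSV_COLUMNS:
                    kwargs[field_name] = float(cell)
                elif col in _INT_CSV_COLUMNS:
                    kwargs[field_name] = int(float(cell))
                elif col in _BOOL_CSV_COLUMNS:
                    kwargs[field_name] = _parse_bool(cell)
                else:
                    kwargs[field_name] = str(cell)
            except (ValueError, ParseError) as exc:
                raise ParseError(
                    f"{path}: row {idx + 1}, column {col!r}: {exc}"
                ) from exc
        try:
            records.append(ResidueRecord(**kwargs))
        except (TypeError, ParseError) as exc:
            raise ParseError(f"{path}: row {idx + 1}: {exc}") from exc
    return records


def _parse_bool(cell) -> bool:
    text = str(cell).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ParseError(f"cannot interpret {cell!r} as boolean")


def write_residue_csv(
    records: Sequence[ResidueRecord],
    path: str | Path,
    metadata: Mapping | None = None,
) -> None:
    """Write residue records as CSV, with optional ``#``-prefixed metadata."""
    rows = []
    for rec in records:
        row = {}
        for f in dataclasses.fields(rec):
            col = _FIELD_TO_CSV.get(f.name, f.name)
            row[col] = getattr(rec, f.name)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(RESIDUE_CSV_COLUMNS))
    with open(path, "w") as fh:
        if metadata:
            fh.write("# " + json.dumps(metadata, sort_keys=True) + "\n")
        df.to_csv(fh, index=False, float_format="%.10g")


def records_to_frame(records: Sequence[ResidueRecord]) -> pd.DataFrame:
    """Residue records as a DataFrame (missing values become NaN/None)."""
    return pd.DataFrame(
        [{f.name: getattr(r, f.name) for f in dataclasses.fields(r)}
         for r in records]
    )


# --------------------------------------------------------------------------
# Model JSON
# --------------------------------------------------------------------------

def write_model_json(fit, path: str | Path, metadata: Mapping | None = None) -> None:
    """Serialize a :class:`~rsalogit.logit_model.LogisticFit` to JSON."""
    payload = {
        "format_version": MODEL_JSON_VERSION,
        "model": fit.to_dict(),
    }
    if metadata:
        payload["metadata"] = dict(metadata)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model_json(path: str | Path):
    """Deserialize a fitted model written by :func:`write_model_json`.

    Validates the schema version and that every declared design column has a
    coefficient.
    """
    from .logit_model import LogisticFit  # deferred: avoid circular import

    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("format_version")
    if version != MODEL_JSON_VERSION:
        raise ParseError(
            f"{path}: model JSON version {version!r} not supported "
            f"(expected {MODEL_JSON_VERSION})"
        )
    if "model" not in payload:
        raise ParseError(f"{path}: missing 'model' key")
    try:
        return LogisticFit.from_dict(payload["model"])
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: malformed model JSON: {exc}") from exc
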