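"""Readers, writers and domain containers for the pipeline's external formats.

Every other module consumes and produces the types defined here:

* :class:`ExpressionMatrix` — genes x arrays log2 expression with a design
  mapping each array to a time group (e.g. days 0, 2, 7, 21, 60 post injury).
* :class:`PromoterSet` — gene-keyed promoter sequences with the extraction
  window recorded (default 1000 bp upstream / 200 bp downstream).
* :class:`PWM` — a 4 x L nucleotide count/weight matrix read from TRANSFAC or
  JASPAR plain-text matrix files.
* :class:`AnnotationSet` — GMT-style gene -> functional-term annotations.

Readers reject malformed inputs with :class:`~chronomics.errors.FormatError`;
invariant violations raise :class:`~chronomics.errors.ValidationError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import FormatError, ValidationError

PROMOTER_ALPHABET = frozenset("ACGTN")
BASES = "ACGT"

__all__ = [
    "ExpressionMatrix",
    "PromoterSet",
    "PWM",
    "AnnotationSet",
    "read_expression",
    "write_expression",
    "read_fasta_promoters",
    "write_fasta_promoters",
    "read_pwms",
    "write_pwms",
    "read_annotations",
    "write_annotations",
]


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x arrays matrix of log2-scale expression with a group design.

    Parameters
    ----------
    gene_ids : list of str
        Unique row identifiers.
    array_ids : list of str
        Unique column identifiers (one per microarray/sample).
    values : ndarray, shape (n_genes, n_arrays)
        Real-valued log2 expression.
    design : mapping array_id -> group label
        Group membership of each array. Group order is the order of first
        appearance and is preserved throughout the pipeline.
    """

    gene_ids: list[str]
    array_ids: list[str]
    values: np.ndarray
    design: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if len(set(self.array_ids)) != len(self.array_ids):
            raise ValidationError("duplicate array ids")
        if self.values.shape != (len(self.gene_ids), len(self.array_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.array_ids)} arrays"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite (missing values unsupported)")
        missing = [a for a in self.array_ids if a not in self.design]
        if missing:
            raise ValidationError(f"arrays absent from design: {missing}")
        groups = self.groups
        if len(groups) < 2:
            raise ValidationError("design must define at least two groups")
        for g, size in zip(groups, self.group_sizes):
            if size < 2:
                raise ValidationError(f"group {g!r} has fewer than two arrays")

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance in the design."""
        seen: dict[str, None] = {}
        for a in self.array_ids:
            seen.setdefault(self.design[a], None)
        return list(seen)

    @property
    def group_sizes(self) -> list[int]:
        labels = [self.design[a] for a in self.array_ids]
        return [labels.count(g) for g in self.groups]

    def group_columns(self) -> dict[str, np.ndarray]:
        """Column indices of each group, keyed by group label."""
        labels = np.array([self.design[a] for a in self.array_ids])
        return {g: np.flatnonzero(labels == g) for g in self.groups}

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_arrays(self) -> int:
        return len(self.array_ids)

    def with_values(self, values: np.ndarray) -> "ExpressionMatrix":
        """Copy with the same ids/design and new values (no re-validation)."""
        values = np.asarray(values, float)
        if values.shape != self.values.shape:
            raise ValidationError("replacement values must keep the shape")
        out = ExpressionMatrix.__new__(ExpressionMatrix)
        out.gene_ids = list(self.gene_ids)
        out.array_ids = list(self.array_ids)
        out.values = values
        out.design = dict(self.design)
        return out

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.array_ids),
                                self.values[rows], dict(self.design))


def read_expression(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated expression matrix and its design table.

    The matrix file has a header row of array ids and a first column of gene
    ids; the design file has columns ``array_id`` and ``group``. Group order
    follows the design file's row order of first appearance.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse expression matrix {path}: {exc}") from exc
    if df.index.has_duplicates:
        raise FormatError("duplicate gene id in expression matrix")
    if df.columns.has_duplicates:
        raise FormatError("duplicate array id in expression matrix")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric cell in expression matrix: {exc}") from exc

    ddf = pd.read_csv(design_path, sep="\t", header=0, dtype=str)
    if not {"array_id", "group"}.issubset(ddf.columns):
        raise FormatError("design table must have columns 'array_id' and 'group'")
    if ddf["array_id"].duplicated().any():
        raise FormatError("duplicate array id in design table")
    design = dict(zip(ddf["array_id"], ddf["group"]))
    missing = [a for a in df.columns if a not in design]
    if missing:
        raise FormatError(f"arrays missing from design table: {missing}")
    # order arrays by design-file row order so group order follows the design
    ordered = [a for a in ddf["array_id"] if a in set(df.columns)]
    df = df[ordered]
    try:
        return ExpressionMatrix(list(df.index), ordered, df.to_numpy(float),
                                {a: design[a] for a in ordered})
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def write_expression(em: ExpressionMatrix, path: str | Path, design_path: str | Path) -> None:
    df = pd.DataFrame(em.values, index=pd.Index(em.gene_ids, name="gene_id"),
                      columns=em.array_ids)
    df.to_csv(path, sep="\t", float_format="%.10g")
    pd.DataFrame({"array_id": em.array_ids,
                  "group": [em.design[a] for a in em.array_ids]}
                 ).to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Promoters
# ---------------------------------------------------------------------------

@dataclass
class PromoterSet:
    """Gene-keyed promoter sequences with their extraction window.

    The window records how the sequences were taken relative to the coding
    start: ``upstream_bp`` before it and ``downstream_bp`` after it
    (defaults 1000/200, i.e. 1200 bp total).
    """

    sequences: dict[str, str]
    upstream_bp: int = 1000
    downstream_bp: int = 200

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValidationError("window lengths must be non-negative")
        for gid, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"empty promoter sequence for {gid!r}")
            if not set(seq) <= PROMOTER_ALPHABET:
                bad = sorted(set(seq) - PROMOTER_ALPHABET)
                raise ValidationError(f"invalid characters {bad} in promoter {gid!r}")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) == 1:
            (L,) = lengths
            expected = self.upstream_bp + self.downstream_bp
            if expected and L != expected:
                raise ValidationError(
                    f"uniform promoter length {L} does not match window "
                    f"{self.upstream_bp}+{self.downstream_bp}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.sequences)

    def subset(self, gene_ids: Iterable[str]) -> "PromoterSet":
        sub = {g: self.sequences[g] for g in gene_ids}
        return PromoterSet(sub, self.upstream_bp, self.downstream_bp)

    def __len__(self) -> int:
        return len(self.sequences)


def read_fasta_promoters(path: str | Path, upstream_bp: int = 1000,
                         downstream_bp: int = 200) -> PromoterSet:
    """Read promoter sequences from FASTA; record ids are gene ids.

    Sequences are uppercased; only A/C/G/T/N are accepted.
    """
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise FormatError(f"duplicate gene id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"empty record {rec.id!r} in {path}")
        if not set(seq) <= PROMOTER_ALPHABET:
            bad = sorted(set(seq) - PROMOTER_ALPHABET)
            raise FormatError(f"invalid characters {bad} in record {rec.id!r}")
        sequences[rec.id] = seq
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    try:
        return PromoterSet(sequences, upstream_bp, downstream_bp)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def write_fasta_promoters(ps: PromoterSet, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for gid, seq in ps.sequences.items():
            fh.write(f">{gid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Position weight matrices
# ---------------------------------------------------------------------------

@dataclass
class PWM:
    """A transcription-factor binding motif as a 4 x L matrix (rows A,C,G,T)."""

    motif_id: str
    matrix: np.ndarray
    dialect: str = "transfac"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise ValidationError(f"PWM {self.motif_id!r}: matrix must be 4 x L")
        if self.matrix.shape[1] < 4:
            raise ValidationError(f"PWM {self.motif_id!r}: motif length must be >= 4")
        if np.any(self.matrix < 0):
            raise ValidationError(f"PWM {self.motif_id!r}: negative entries")
        if np.any(self.matrix.sum(axis=0) == 0):
            raise ValidationError(f"PWM {self.motif_id!r}: all-zero column")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]


def _parse_transfac(text: str) -> list[PWM]:
    pwms: list[PWM] = []
    blocks = [b for b in text.split("//") if b.strip()]
    for block in blocks:
        name_id = name_na = None
        rows: list[list[float]] = []
        for line in block.splitlines():
            line = line.rstrip()
            if not line:
                continue
            tag, _, rest = line.partition(" ")
            rest = rest.strip()
            if tag == "ID" and rest:
                name_id = rest.split()[0]
            elif tag == "NA" and rest:
                name_na = rest.split()[0]
            elif tag == "P0" or tag == "PO":
                continue
            elif tag.isdigit():
                parts = rest.split()
                # trailing consensus letter is optional
                if parts and not _is_number(parts[-1]):
                    parts = parts[:-1]
                if len(parts) != 4:
                    raise FormatError(
                        f"TRANSFAC matrix line {line!r}: expected 4 counts")
                try:
                    rows.append([float(x) for x in parts])
                except ValueError as exc:
                    raise FormatError(f"non-numeric count in line {line!r}") from exc
        if not rows:
            if name_id or name_na:
                raise FormatError(f"TRANSFAC block {name_na or name_id!r} has no matrix")
            continue
        name = name_na or name_id
        if name is None:
            raise FormatError("TRANSFAC block without ID/NA line")
        matrix = np.array(rows, dtype=float).T  # file rows are positions
        try:
            pwms.append(PWM(name, matrix, "transfac"))
        except ValidationError as exc:
            raise FormatError(str(exc)) from exc
    return pwms


def _is_number(tok: str) -> bool:
    try:
        float(tok)
    except ValueError:
        return False
    return True


def _parse_jaspar(text: str) -> list[PWM]:
    pwms: list[PWM] = []
    name = None
    rows: dict[str, list[float]] = {}

    def flush() -> None:
        nonlocal rows, name
        if name is None and not rows:
            return
        if set(rows) != set(BASES):
            raise FormatError(f"JASPAR block {name!r}: need rows A,C,G,T, got {sorted(rows)}")
        lens = {len(v) for v in rows.values()}
        if len(lens) != 1:
            raise FormatError(f"JASPAR block {name!r}: ragged matrix rows")
        matrix = np.array([rows[b] for b in BASES], dtype=float)
        try:
            pwms.append(PWM(name, matrix, "jaspar"))
        except ValidationError as exc:
            raise FormatError(str(exc)) from exc
        rows = {}
        name = None

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if name is not None or rows:
                flush()
            name = line[1:].split()[0] if line[1:].split() else None
            if name is None:
                raise FormatError("JASPAR header '>' without a motif id")
        else:
            base = line[0].upper()
            if base not in BASES:
                raise FormatError(f"unexpected JASPAR line {line!r}")
            body = line[1:].replace("[", " ").replace("]", " ")
            try:
                vals = [float(x) for x in body.split()]
            except ValueError as exc:
                raise FormatError(f"non-numeric count in line {line!r}") from exc
            if base in rows:
                raise FormatError(f"duplicate row {base!r} in JASPAR block {name!r}")
            rows[base] = vals
    if name is not None or rows:
        flush()
    return pwms


def read_pwms(path: str | Path, dialect: str) -> list[PWM]:
    """Parse a TRANSFAC or JASPAR plain-text matrix file into PWMs.

    TRANSFAC blocks are ``//``-delimited with numbered position lines of four
    counts (plus an optional consensus letter) and take their name from the
    ``NA`` line, falling back to ``ID``. JASPAR blocks are a ``>`` header
    followed by four ``A [ ... ]``-style rows.
    """
    if dialect not in ("transfac", "jaspar"):
        raise FormatError(f"unknown PWM dialect {dialect!r}")
    text = Path(path).read_text()
    pwms = _parse_transfac(text) if dialect == "transfac" else _parse_jaspar(text)
    if not pwms:
        raise FormatError(f"no motifs found in {path}")
    ids = [p.motif_id for p in pwms]
    if len(set(ids)) != len(ids):
        raise FormatError(f"duplicate motif ids in {path}")
    return pwms


def write_pwms(pwms: Sequence[PWM], path: str | Path, dialect: str = "transfac") -> None:
    if dialect not in ("transfac", "jaspar"):
        raise FormatError(f"unknown PWM dialect {dialect!r}")
    with open(path, "w") as fh:
        for pwm in pwms:
            if dialect == "transfac":
                fh.write(f"NA {pwm.motif_id}\n")
                fh.write("P0 A C G T\n")
                for i in range(pwm.length):
                    counts = " ".join("%.6g" % v for v in pwm.matrix[:, i])
                    fh.write(f"{i + 1:02d} {counts}\n")
                fh.write("//\n")
            else:
                fh.write(f">{pwm.motif_id}\n")
                for b, row in zip(BASES, pwm.matrix):
                    fh.write(f"{b} [ " + " ".join("%.6g" % v for v in row) + " ]\n")


# ---------------------------------------------------------------------------
# Annotations (GMT)
# ---------------------------------------------------------------------------

@dataclass
class AnnotationTerm:
    term_id: str
    term_class: str
    description: str
    members: list[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"term {self.term_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"term {self.term_id!r} has duplicate members")


@dataclass
class AnnotationSet:
    """A collection of functional-annotation terms (GO/KEGG/INTERPRO-style)."""

    terms: list[AnnotationTerm] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate term ids in annotation set")

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms)


def read_annotations(path: str | Path) -> AnnotationSet:
    """Read GMT-style annotations: term_id <tab> class|description <tab> genes...

    The second column carries an optional class tag separated from the
    description by ``|`` (e.g. ``GO_BP|synaptic transmission``); without a
    ``|`` the class is empty. Duplicate members within a row are stored once.
    """
    terms: list[AnnotationTerm] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT rows need >= 3 columns")
            term_id, desc = parts[0], parts[1]
            term_class, _, description = desc.partition("|")
            if not _:
                term_class, description = "", desc
            members = [g for g in parts[2:] if g]
            if not members:
                raise FormatError(f"{path}:{ln}: term {term_id!r} has no members")
            deduped = list(dict.fromkeys(members))
            terms.append(AnnotationTerm(term_id, term_class, description, deduped))
    if not terms:
        raise FormatError(f"no annotation rows in {path}")
    try:
        return AnnotationSet(terms)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def write_annotations(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in ann.terms:
            desc = f"{t.term_class}|{t.description}" if t.term_class else t.description
            fh.write("\t".join([t.term_id, desc, *t.members]) + "\n")
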