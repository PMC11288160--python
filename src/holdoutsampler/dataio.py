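"""Reading and writing the tabular and alignment formats the tool touches.

The canonical feature-table dialect is a TSV with a header row.  Mandatory
columns are ``id, protein, position, wt, mut, label``; every remaining column
must be named ``<group>.<name>`` where ``<group>`` is one of the six attribute
families sampled by the holdout sampler (``sequence``, ``sequence_profile``,
``mutation``, ``evolutionary``, ``structural``, ``stability``).  Labels are the
strings ``deleterious`` / ``neutral`` / ``unknown``, encoded internally as
1 / 0 / -1 with *deleterious* as the positive class throughout the package.

All 20-vectors over amino acids use the alphabetical single-letter order
``A C D E F G H I K L M N P Q R S T V W Y``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ContractError, FormatError

logger = logging.getLogger(__name__)

#: Canonical amino-acid order for every 20-vector in the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: The six attribute families of the sampler.
GROUPS = (
    "sequence",
    "sequence_profile",
    "mutation",
    "evolutionary",
    "structural",
    "stability",
)

LABEL_TO_INT = {"deleterious": 1, "neutral": 0, "unknown": -1}
INT_TO_LABEL = {v: k for k, v in LABEL_TO_INT.items()}

MANDATORY_COLUMNS = ("id", "protein", "position", "wt", "mut", "label")


@dataclass(frozen=True)
class MutationRecord:
    """One single amino acid polymorphism (nsSNV at the protein level)."""

    protein_id: str
    position: int  # 1-based residue index in the wild-type sequence
    wt: str
    mut: str
    label: str = "unknown"

    def validation_error(self) -> str | None:
        """Return a message describing the first violated invariant, or None."""
        if self.wt not in AA_INDEX:
            return f"wild-type residue {self.wt!r} not a canonical amino acid"
        if self.mut not in AA_INDEX:
            return f"mutant residue {self.mut!r} not a canonical amino acid"
        if self.wt == self.mut:
            return f"wt == mut ({self.wt}) is not a substitution"
        if self.position < 1:
            return f"position {self.position} is not 1-based"
        if self.label not in LABEL_TO_INT:
            return f"unknown label {self.label!r}"
        return None

    @property
    def sample_id(self) -> str:
        return f"{self.protein_id}:{self.wt}{self.position}{self.mut}"


@dataclass
class FeatureMatrix:
    """Samples x named numeric attributes, each attribute tagged with a group.

    ``labels`` uses the encoding deleterious=1, neutral=0, unknown=-1.
    """

    sample_ids: list[str]
    X: np.ndarray  # (n_samples, n_attributes) float64, no NaN
    attribute_names: list[str]
    attribute_groups: dict[str, str]
    labels: np.ndarray  # (n_samples,) int
    records: list[MutationRecord] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n, p = self.X.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise ContractError("sample_ids / labels length must match matrix rows")
        if len(self.attribute_names) != p:
            raise ContractError("attribute_names length must match matrix columns")
        if len(set(self.attribute_names)) != p:
            raise ContractError("attribute names must be unique")
        for name in self.attribute_names:
            group = self.attribute_groups.get(name)
            if group not in GROUPS:
                raise ContractError(f"attribute {name!r} has invalid group {group!r}")
        if not np.all(np.isfinite(self.X)):
            raise ContractError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.X.shape[1]

    @property
    def groups_present(self) -> tuple[str, ...]:
        present = {self.attribute_groups[a] for a in self.attribute_names}
        return tuple(g for g in GROUPS if g in present)

    def columns_for_groups(self, groups) -> np.ndarray:
        """Indices of attribute columns belonging to any of *groups*."""
        wanted = set(groups)
        idx = [
            j
            for j, name in enumerate(self.attribute_names)
            if self.attribute_groups[name] in wanted
        ]
        return np.asarray(idx, dtype=int)

    def subset(self, rows) -> "FeatureMatrix":
        """Row-subset view (copies) preserving attribute metadata."""
        rows = np.asarray(rows, dtype=int)
        return FeatureMatrix(
            sample_ids=[self.sample_ids[i] for i in rows],
            X=self.X[rows].copy(),
            attribute_names=list(self.attribute_names),
            attribute_groups=dict(self.attribute_groups),
            labels=self.labels[rows].copy(),
            records=[self.records[i] for i in rows] if self.records else None,
        )

    def to_frame(self) -> pd.DataFrame:
        """Render as the canonical TSV dialect (one row per sample)."""
        meta: dict[str, list] = {c: [] for c in MANDATORY_COLUMNS}
        records = self.records
        for i, sid in enumerate(self.sample_ids):
            rec = records[i] if records else None
            meta["id"].append(sid)
            meta["protein"].append(rec.protein_id if rec else sid.split(":")[0])
            meta["position"].append(rec.position if rec else 1)
            meta["wt"].append(rec.wt if rec else "A")
            meta["mut"].append(rec.mut if rec else "C")
            meta["label"].append(INT_TO_LABEL[int(self.labels[i])])
        frame = pd.DataFrame(meta)
        for j, name in enumerate(self.attribute_names):
            frame[name] = self.X[:, j]
        return frame


def _records_from_frame(frame: pd.DataFrame) -> list[MutationRecord]:
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            MutationRecord(
                protein_id=str(row.protein),
                position=int(row.position),
                wt=str(row.wt),
                mut=str(row.mut),
                label=str(row.label),
            )
        )
    return records


def read_feature_table(path, *, strict: bool = False, sep: str = "\t") -> FeatureMatrix:
    """Parse a mutation feature table into a validated :class:`FeatureMatrix`.

    Rows violating the substitution invariants (wt == mut, non-canonical
    residues, position < 1, unknown label) are dropped with a logged count;
    under ``strict=True`` they raise :class:`FormatError` instead.  Missing
    numeric cells are imputed with the column median (strict mode rejects).
    """
    frame = pd.read_csv(path, sep=sep, dtype={"protein": str, "id": str})
    missing = [c for c in MANDATORY_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")

    attr_cols = [c for c in frame.columns if c not in MANDATORY_COLUMNS]
    for col in attr_cols:
        prefix = col.split(".", 1)[0]
        if "." not in col or prefix not in GROUPS:
            raise FormatError(
                f"attribute column {col!r} must be named <group>.<name> with "
                f"group in {GROUPS}"
            )

    # Numeric coercion with strict provenance of failures.
    for col in attr_cols:
        raw = frame[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        if strict:
            bad = coerced.isna() & raw.notna()
            if bad.any():
                i = int(np.flatnonzero(bad.to_numpy())[0])
                raise FormatError(
                    f"non-numeric value {raw.iloc[i]!r} at row {i}, column {col!r}"
                )
        frame[col] = coerced

    records = _records_from_frame(frame)
    bad_rows = [i for i, r in enumerate(records) if r.validation_error() is not None]
    if bad_rows:
        if strict:
            i = bad_rows[0]
            raise FormatError(f"row {i}: {records[i].validation_error()}")
        logger.warning("dropping %d row(s) failing mutation-record validation", len(bad_rows))
        frame = frame.drop(index=frame.index[bad_rows]).reset_index(drop=True)
        records = [r for i, r in enumerate(records) if i not in set(bad_rows)]

    X = frame[attr_cols].to_numpy(dtype=float)
    if np.isnan(X).any():
        if strict:
            i, j = map(int, np.argwhere(np.isnan(X))[0])
            raise FormatError(f"missing value at row {i}, column {attr_cols[j]!r}")
        medians = np.nanmedian(X, axis=0)
        if np.isnan(medians).any():
            j = int(np.flatnonzero(np.isnan(medians))[0])
            raise FormatError(f"column {attr_cols[j]!r} has no observed values")
        nan_r, nan_c = np.nonzero(np.isnan(X))
        X[nan_r, nan_c] = medians[nan_c]
        logger.warning("imputed %d missing cell(s) with column medians", len(nan_r))

    labels = np.array([LABEL_TO_INT[r.label] for r in records], dtype=int)
    return FeatureMatrix(
        sample_ids=[str(v) for v in frame["id"]],
        X=X,
        attribute_names=attr_cols,
        attribute_groups={c: c.split(".", 1)[0] for c in attr_cols},
        labels=labels,
        records=records,
    )


def write_feature_table(matrix: FeatureMatrix, path, *, sep: str = "\t") -> None:
    """Write *matrix* in the canonical TSV dialect (round-trips exactly)."""
    matrix.to_frame().to_csv(path, sep=sep, index=False)


@dataclass
class Alignment:
    """A multiple sequence alignment; the first record is the query."""

    ids: list[str]
    sequences: list[str]  # equal length, alphabet = 20 aa + '-'
    query_index: int = 0

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def query(self) -> str:
        return self.sequences[self.query_index]


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file; all records must have equal length."""
    seqs, ids = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if not seqs:
        raise FormatError(f"no sequences in alignment file {path}")
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise FormatError(
            f"ragged alignment in {path}: sequence lengths {sorted(lengths)}"
        )
    return Alignment(ids=ids, sequences=seqs, query_index=0)


def write_predictions(records, scores, classes, path) -> None:
    """Write consensus predictions as a TSV.

    Columns: id, protein, position, wt, mut, consensus_score, predicted_class.
    Scores are rendered with 6 decimal places.
    """
    records = list(records)
    scores = np.asarray(scores, dtype=float)
    classes = np.asarray(classes, dtype=int)
    if not (len(records) == len(scores) == len(classes)):
        raise ContractError(
            f"length mismatch: {len(records)} records, {len(scores)} scores, "
            f"{len(classes)} classes"
        )
    frame = pd.DataFrame(
        {
            "id": [r.sample_id for r in records],
            "protein": [r.protein_id for r in records],
            "position": [r.position for r in records],
            "wt": [r.wt for r in records],
            "mut": [r.mut for r in records],
            "consensus_score": [f"{s:.6f}" for s in scores],
            "predicted_class": [INT_TO_LABEL[int(c)] for c in classes],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
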