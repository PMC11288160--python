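"""In-repo attribute encodings for single amino acid substitutions.

Two encodings are computed here rather than ingested:

* the *mutation vector* — a 20-vector with -1 at the wild-type residue, +1 at
  the mutant residue and 0 elsewhere;
* the *sequence profile* — per-alignment-column amino-acid frequencies from a
  multiple alignment of homologs, of which the row at the mutated position is
  used as the 20 ``sequence_profile.*`` attributes.

Everything else (alignment scores, conservation times, solvent accessibility,
stability changes) arrives as precomputed ``<group>.<name>`` columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import AA_INDEX, AMINO_ACIDS, Alignment, FeatureMatrix, LABEL_TO_INT, MutationRecord
from .errors import ContractError

logger = logging.getLogger(__name__)

MUTATION_ATTRS = [f"mutation.{aa}" for aa in AMINO_ACIDS]
PROFILE_ATTRS = [f"sequence_profile.{aa}" for aa in AMINO_ACIDS]


def mutation_vector(wt: str, mut: str) -> np.ndarray:
    """Encode the substitution wt→mut as a 20-vector (-1 wt, +1 mut, 0 rest)."""
    if wt not in AA_INDEX or mut not in AA_INDEX:
        raise ContractError(f"non-canonical residue in substitution {wt!r}->{mut!r}")
    if wt == mut:
        raise ContractError(f"wt == mut ({wt}) is not a substitution")
    vec = np.zeros(20)
    vec[AA_INDEX[wt]] = -1.0
    vec[AA_INDEX[mut]] = 1.0
    return vec


@dataclass
class SequenceProfile:
    """Per-column amino-acid frequencies of an alignment, plus the gapped query.

    ``freq`` has one row per alignment column; each row is a distribution over
    the 20 canonical residues (gaps excluded from the denominator; an all-gap
    column is uniform 1/20).
    """

    freq: np.ndarray  # (alignment length, 20)
    query: str  # gapped query sequence, same length as freq

    @property
    def query_length(self) -> int:
        """Length of the ungapped query sequence."""
        return sum(1 for c in self.query if c != "-")

    def query_column(self, position: int) -> int:
        """Alignment column of a 1-based position in the ungapped query."""
        if position < 1:
            raise ContractError(f"position {position} is not 1-based")
        seen = 0
        for col, c in enumerate(self.query):
            if c != "-":
                seen += 1
                if seen == position:
                    return col
        raise ContractError(
            f"position {position} beyond query length {self.query_length}"
        )


def sequence_profile(alignment: Alignment, *, pseudocount: float = 0.0) -> SequenceProfile:
    """Empirical per-column amino-acid frequencies of *alignment*.

    Gaps are excluded from the denominator; non-canonical letters (X, B, ...)
    are ignored like gaps.  ``pseudocount`` adds a Dirichlet prior count per
    residue (default 0: raw frequencies).
    """
    L = alignment.length
    counts = np.zeros((L, 20))
    for seq in alignment.sequences:
        for col, c in enumerate(seq):
            idx = AA_INDEX.get(c)
            if idx is not None:
                counts[col, idx] += 1.0
    counts += pseudocount
    totals = counts.sum(axis=1, keepdims=True)
    all_gap = totals[:, 0] == 0
    if all_gap.any():
        logger.warning(
            "%d all-gap alignment column(s); using uniform 1/20", int(all_gap.sum())
        )
        counts[all_gap] = 1.0
        totals = counts.sum(axis=1, keepdims=True)
    return SequenceProfile(freq=counts / totals, query=alignment.query)


def profile_at(profile: SequenceProfile, position: int) -> np.ndarray:
    """Frequency row for a 1-based position in the ungapped query sequence."""
    return profile.freq[profile.query_column(position)].copy()


def assemble_features(
    records: list[MutationRecord],
    profiles: dict[str, SequenceProfile] | None = None,
    aux: pd.DataFrame | None = None,
    *,
    strict: bool = False,
) -> FeatureMatrix:
    """Build one feature row per mutation record.

    Each row is the concatenation of the 20-value mutation vector, the 20-value
    profile row at the mutated position (when *profiles* is given), and any
    precomputed *aux* columns (named ``<group>.<name>``, one row per record).

    When a profile is available, the query residue at the mutated position is
    checked against the record's wild type; a mismatch logs a warning (strict
    mode drops the record).
    """
    records = list(records)
    if aux is not None and len(aux) != len(records):
        raise ContractError(
            f"aux table has {len(aux)} rows for {len(records)} records"
        )
    if profiles is not None:
        missing = sorted({r.protein_id for r in records} - set(profiles))
        if missing:
            raise ContractError(f"no profile for protein(s): {', '.join(missing)}")

    keep = np.ones(len(records), dtype=bool)
    blocks = []
    for i, rec in enumerate(records):
        row = [mutation_vector(rec.wt, rec.mut)]
        if profiles is not None:
            prof = profiles[rec.protein_id]
            col = prof.query_column(rec.position)
            query_res = prof.query[col]
            if query_res != rec.wt:
                msg = (
                    f"record {rec.sample_id}: query residue {query_res} at position "
                    f"{rec.position} does not match wild type {rec.wt}"
                )
                if strict:
                    logger.warning("%s; dropping record", msg)
                    keep[i] = False
                else:
                    logger.warning(msg)
            row.append(prof.freq[col])
        blocks.append(np.concatenate(row))

    names = list(MUTATION_ATTRS)
    if profiles is not None:
        names += PROFILE_ATTRS
    if aux is not None:
        from .dataio import GROUPS

        for col in aux.columns:
            if "." not in col or col.split(".", 1)[0] not in GROUPS:
                raise ContractError(f"aux column {col!r} lacks a valid group prefix")
        names += list(aux.columns)
    if records:
        X = np.asarray(blocks)
        if aux is not None:
            X = np.hstack([X, aux.to_numpy(dtype=float)])
    else:
        X = np.empty((0, len(names)))

    X = X[keep]
    kept_records = [r for r, k in zip(records, keep) if k]
    return FeatureMatrix(
        sample_ids=[r.sample_id for r in kept_records],
        X=X,
        attribute_names=names,
        attribute_groups={n: n.split(".", 1)[0] for n in names},
        labels=np.array([LABEL_TO_INT[r.label] for r in kept_records], dtype=int),
        records=kept_records,
    )
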