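"""Synthetic labeled mutation feature tables with planted group effects.

The generator emulates the statistical shape of a curated nsSNV training set:
two moderately imbalanced classes and six attribute groups of differing
discriminative power, with pure-noise attributes mixed in.  Five of the
groups carry Gaussian class-conditional attributes N(d_g * label, noise_sd),
where d_g is the group's standardized effect size.  The ``mutation`` group is
special: its 20 columns are rendered as *valid mutation vectors* (-1 wild
type, +1 mutant, 0 elsewhere) whose mutant residue is drawn from a
label-dependent categorical distribution with concentration d_mutation, so
the encoding invariants hold while the group's discriminative power still
scales with its effect size.

Default effects mirror the qualitative ranking seen in real nsSNV data:
mutation and sequence-profile attributes strong, evolutionary and structural
moderate, stability null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import AMINO_ACIDS, Alignment, FeatureMatrix, INT_TO_LABEL, MutationRecord
from .errors import ContractError
from .features import mutation_vector

DEFAULT_GROUP_EFFECTS = {
    "sequence": 0.3,
    "sequence_profile": 0.8,
    "mutation": 1.5,
    "evolutionary": 0.5,
    "structural": 0.4,
    "stability": 0.0,
}

DEFAULT_ATTRS_PER_GROUP = {
    "sequence": 3,  # alignment score, alignment ratio, aligned-sequence count
    "sequence_profile": 20,
    "mutation": 20,
    "evolutionary": 1,  # conservation time
    "structural": 1,  # solvent accessible area
    "stability": 1,  # stability change
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset."""

    n_samples: int = 1000
    class_balance: float = 0.35  # fraction deleterious
    group_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS)
    )
    attrs_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ATTRS_PER_GROUP)
    )
    noise_sd: float = 1.0
    heavy_tails: bool = False  # t(3) noise instead of Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.class_balance < 1:
            raise ContractError(f"class_balance {self.class_balance} outside (0, 1)")
        if self.n_samples < 1:
            raise ContractError("n_samples must be >= 1")
        if self.noise_sd <= 0:
            raise ContractError("noise_sd must be positive")
        for g, d in self.group_effects.items():
            if d < 0:
                raise ContractError(f"negative effect size for group {g!r}")
        for g, k in self.attrs_per_group.items():
            if k < 1:
                raise ContractError(f"attrs_per_group[{g!r}] must be >= 1")
        if "mutation" in self.attrs_per_group and self.attrs_per_group["mutation"] != 20:
            raise ContractError("the mutation group is always the 20-vector encoding")


def _mutant_weights(label: int, d: float) -> np.ndarray:
    """Categorical weights over mutant residues; the first 10 residues are
    enriched under the deleterious class with concentration d."""
    sign = np.where(np.arange(20) < 10, 1.0, -1.0)
    w = np.exp((d if label == 1 else -d) * sign)
    return w / w.sum()


def generate_dataset(config: GeneratorConfig) -> tuple[FeatureMatrix, dict[str, float]]:
    """Draw a labeled FeatureMatrix plus the planted per-group effect sizes.

    Labels are Bernoulli(class_balance); Gaussian groups get a d_g * label
    mean shift at scale noise_sd; mutation columns are valid mutation vectors
    with a label-correlated mutant-residue choice.  Fully reproducible from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    labels = (rng.random(n) < config.class_balance).astype(int)

    names: list[str] = []
    blocks: list[np.ndarray] = []
    records: list[MutationRecord] = []

    groups = [g for g in config.attrs_per_group]
    # mutation vectors + the per-sample wt/mut bookkeeping
    if "mutation" in groups:
        d_mut = config.group_effects.get("mutation", 0.0)
        weights = {lab: _mutant_weights(lab, d_mut) for lab in (0, 1)}
        mut_block = np.zeros((n, 20))
        for i in range(n):
            mut = int(rng.choice(20, p=weights[labels[i]]))
            wt = int(rng.integers(19))
            if wt >= mut:
                wt += 1  # uniform over the 19 residues != mut
            mut_block[i] = mutation_vector(AMINO_ACIDS[wt], AMINO_ACIDS[mut])
            records.append(
                MutationRecord(
                    protein_id=f"P{i % max(n // 4, 1):05d}",
                    position=int(rng.integers(1, 500)),
                    wt=AMINO_ACIDS[wt],
                    mut=AMINO_ACIDS[mut],
                    label=INT_TO_LABEL[int(labels[i])],
                )
            )
        names += [f"mutation.{aa}" for aa in AMINO_ACIDS]
        blocks.append(mut_block)
    else:
        for i in range(n):
            wt = int(rng.integers(20))
            mut = (wt + 1 + int(rng.integers(19))) % 20
            records.append(
                MutationRecord(
                    protein_id=f"P{i % max(n // 4, 1):05d}",
                    position=int(rng.integers(1, 500)),
                    wt=AMINO_ACIDS[wt],
                    mut=AMINO_ACIDS[mut],
                    label=INT_TO_LABEL[int(labels[i])],
                )
            )

    for g in groups:
        if g == "mutation":
            continue
        k = config.attrs_per_group[g]
        d = config.group_effects.get(g, 0.0)
        if config.heavy_tails:
            noise = rng.standard_t(df=3, size=(n, k)) / np.sqrt(3.0)
        else:
            noise = rng.standard_normal((n, k))
        block = config.noise_sd * (noise + d * labels[:, None])
        names += [f"{g}.a{j:02d}" for j in range(k)]
        blocks.append(block)

    matrix = FeatureMatrix(
        sample_ids=[r.sample_id + f"#{i}" for i, r in enumerate(records)],
        X=np.hstack(blocks),
        attribute_names=names,
        attribute_groups={c: c.split(".", 1)[0] for c in names},
        labels=labels,
        records=records,
    )
    truth = {g: float(config.group_effects.get(g, 0.0)) for g in groups}
    return matrix, truth


def generate_toy_alignment(
    n_seqs: int,
    length: int,
    conservation,
    seed: int = 0,
    *,
    gap_frac: float = 0.0,
) -> Alignment:
    """Toy multiple alignment: each column mixes a consensus residue
    (probability = that column's conservation) with uniform residue noise.

    ``conservation`` is a scalar or a per-column array in [0, 1]; gaps are
    injected uniformly at ``gap_frac`` in the non-query rows.
    """
    if n_seqs < 1 or length < 1:
        raise ContractError("n_seqs and length must be >= 1")
    cons = np.broadcast_to(np.asarray(conservation, dtype=float), (length,))
    if np.any((cons < 0) | (cons > 1)):
        raise ContractError("conservation must lie in [0, 1]")
    if not 0 <= gap_frac < 1:
        raise ContractError("gap_frac must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    consensus = rng.integers(0, 20, size=length)
    rows = []
    for s in range(n_seqs):
        residues = np.where(
            rng.random(length) < cons, consensus, rng.integers(0, 20, size=length)
        )
        chars = [AMINO_ACIDS[r] for r in residues]
        if gap_frac > 0 and s > 0:  # keep the query gap-free
            gaps = rng.random(length) < gap_frac
            chars = ["-" if g else c for c, g in zip(chars, gaps)]
        rows.append("".join(chars))
    return Alignment(ids=[f"seq{t}" for t in range(n_seqs)], sequences=rows)
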