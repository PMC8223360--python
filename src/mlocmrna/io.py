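"""Sequence and label I/O, dataset construction.

Covers the corpus-preparation protocol: reading FASTA and label tables,
normalising to the DNA alphabet, dropping multi-location records, greedy
redundancy reduction at a pairwise-identity threshold, the train/independent
split, and the assembly of one-vs-rest binary datasets (positives = one
location, negatives = the union of the remaining locations).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner

logger = logging.getLogger(__name__)

#: The nine localization classes, in the fixed order used everywhere
#: downstream (model columns, reports).
DEFAULT_LOCALIZATIONS = (
    "cytoplasm",
    "cytosol",
    "endoplasmic_reticulum",
    "exosome",
    "mitochondrion",
    "nucleus",
    "pseudopodium",
    "posterior",
    "ribosome",
)

_VALID_CHARS = frozenset("ACGTN")


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One normalized nucleotide sequence with its localization labels."""

    id: str
    sequence: str
    labels: frozenset = frozenset()

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if not isinstance(self.labels, frozenset):
            object.__setattr__(self, "labels", frozenset(self.labels))


@dataclass(frozen=True)
class LocalizationCatalog:
    """Ordered, unique list of localization class names."""

    names: tuple = DEFAULT_LOCALIZATIONS

    def __post_init__(self):
        names = tuple(self.names)
        if len(set(names)) != len(names):
            raise ValueError("localization names must be unique")
        object.__setattr__(self, "names", names)

    def __iter__(self):
        return iter(self.names)

    def __len__(self):
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass
class LocalizedDataset:
    """Records plus the catalog their labels are validated against."""

    records: list
    catalog: LocalizationCatalog = field(default_factory=LocalizationCatalog)

    def __post_init__(self):
        seen = set()
        valid = set(self.catalog.names)
        for rec in self.records:
            if rec.id in seen:
                raise ValueError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            bad = set(rec.labels) - valid
            if bad:
                raise ValueError(
                    f"record {rec.id!r}: labels not in catalog: {sorted(bad)}"
                )

    def __len__(self):
        return len(self.records)


@dataclass
class BinaryDataset:
    """One-vs-rest dataset for a single localization."""

    localization: str
    positives: list
    negatives: list

    def __post_init__(self):
        pos_ids = {r.id for r in self.positives}
        overlap = pos_ids & {r.id for r in self.negatives}
        if overlap:
            raise ValueError(
                f"{self.localization}: records in both classes: {sorted(overlap)[:5]}"
            )
        for r in self.positives:
            if self.localization not in r.labels:
                raise ValueError(
                    f"{self.localization}: positive {r.id!r} lacks the label"
                )
        for r in self.negatives:
            if self.localization in r.labels:
                raise ValueError(
                    f"{self.localization}: negative {r.id!r} carries the label"
                )


def normalize_sequence(raw: str) -> str:
    """Normalize a raw nucleotide string to the {A,C,G,T,N} alphabet.

    Uppercases, maps U to T (RNA input is tolerated), keeps ambiguous N
    (handled at featurization), and rejects anything else with the offending
    character and 1-based position.
    """
    seq = raw.strip().upper().replace("U", "T")
    if not seq:
        raise ValueError("sequence empty after stripping whitespace")
    for i, ch in enumerate(seq):
        if ch not in _VALID_CHARS:
            raise ValueError(f"illegal character {ch!r} at position {i + 1}")
    return seq


def read_fasta(path) -> list:
    """Read a FASTA file into raw ``(id, sequence)`` pairs.

    Multi-line sequences are concatenated; the description after the first
    whitespace is dropped from the id. Errors on text before the first
    header (with its line number) and on duplicate ids.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(";"):
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before first header"
                )
            break
    pairs = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        pairs.append((rec.id, str(rec.seq)))
    return pairs


def read_label_table(path, catalog: LocalizationCatalog | None = None) -> dict:
    """Read a two-column TSV (seq_id, comma-separated localizations).

    Label names are case-folded; unknown names raise with the full list of
    offenders.
    """
    if catalog is None:
        catalog = LocalizationCatalog()
    valid = {n.lower(): n for n in catalog.names}
    labels: dict = {}
    offenders = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 tab-separated columns")
            seq_id, raw_labels = parts[0].strip(), parts[1]
            if seq_id == "seq_id":  # header row
                continue
            names = set()
            for token in raw_labels.split(","):
                token = token.strip().lower()
                if not token:
                    continue
                if token not in valid:
                    offenders.append((seq_id, token))
                else:
                    names.add(valid[token])
            labels[seq_id] = frozenset(names)
    if offenders:
        raise ValueError(f"{path}: unknown localization names: {offenders}")
    return labels


def collapse_identical_sequences(ds: LocalizedDataset) -> LocalizedDataset:
    """Merge records whose sequence strings are byte-identical.

    The first id is kept and labels are unioned; collapses are logged. Run
    before overlap removal so the same molecule under two accessions counts
    once.
    """
    by_seq: dict = {}
    order = []
    for rec in ds.records:
        if rec.sequence in by_seq:
            prev = by_seq[rec.sequence]
            logger.info("collapsing %s into %s (identical sequence)", rec.id, prev.id)
            by_seq[rec.sequence] = SequenceRecord(
                prev.id, prev.sequence, prev.labels | rec.labels
            )
        else:
            by_seq[rec.sequence] = rec
            order.append(rec.sequence)
    return LocalizedDataset([by_seq[s] for s in order], ds.catalog)


def overlap_summary(ds: LocalizedDataset) -> Counter:
    """Count records per label combination (multi-location membership table)."""
    return Counter(tuple(sorted(rec.labels)) for rec in ds.records)


def remove_overlapping(ds: LocalizedDataset) -> LocalizedDataset:
    """Keep only records assigned to exactly one localization.

    Identical sequence strings are collapsed first; the per-combination
    removal counts are logged. Idempotent.
    """
    ds = collapse_identical_sequences(ds)
    kept, removed = [], Counter()
    for rec in ds.records:
        if len(rec.labels) == 1:
            kept.append(rec)
        else:
            removed[tuple(sorted(rec.labels))] += 1
    for combo, n in sorted(removed.items()):
        logger.info("overlap removal: dropped %d records with labels %s", n, combo)
    if not kept:
        warnings.warn("all records were multi-label; dataset is empty")
    return LocalizedDataset(kept, ds.catalog)


@dataclass
class RedundancyResult:
    retained: list
    removed: list
    representatives: dict  # removed id -> retained representative id

    def __iter__(self):  # allow (retained, removed) unpacking
        return iter((self.retained, self.removed))


def pairwise_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    """Global-alignment identity: matched positions / shorter-sequence length.

    Scoring is match=1, mismatch=0 with mild gap penalties, so the alignment
    maximizes matched positions while preferring contiguous runs.
    """
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(a, b)[0]
    identities = aln.counts().identities
    return identities / min(len(a), len(b))


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    return aligner


def reduce_redundancy(records, identity_threshold: float = 0.8) -> RedundancyResult:
    """Greedy redundancy reduction at a pairwise-identity cut-off.

    Records are sorted by descending length; each is compared against the
    retained representatives whose length passes the length-ratio pre-filter
    (shorter/longer >= threshold), and removed when identity to any
    representative reaches the threshold. The removed list is preserved — it
    forms the similarity-sharing second independent test set.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    aligner = _make_aligner()
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    retained: list = []
    removed: list = []
    reps: dict = {}
    for rec in ordered:
        hit = None
        for rep in retained:
            # representatives are at least as long as rec
            if len(rec.sequence) < identity_threshold * len(rep.sequence):
                continue
            if pairwise_identity(rec.sequence, rep.sequence, aligner) >= identity_threshold:
                hit = rep
                break
        if hit is None:
            retained.append(rec)
        else:
            removed.append(rec)
            reps[rec.id] = hit.id
    return RedundancyResult(retained, removed, reps)


def split_train_independent(records, n_subsets: int = 6, seed: int = 0):
    """Shuffle, partition into ``n_subsets`` near-equal parts, hold one out.

    One randomly drawn part becomes the independent set; the rest are the
    training pool. Part sizes differ by at most one; deterministic given
    ``seed``.
    """
    if n_subsets < 2:
        raise ValueError("n_subsets must be >= 2")
    if len(records) < n_subsets:
        raise ValueError(
            f"need at least {n_subsets} records to split, got {len(records)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    parts = np.array_split(order, n_subsets)
    held = int(rng.integers(n_subsets))
    independent = [records[i] for i in parts[held]]
    train = [records[i] for j, part in enumerate(parts) if j != held for i in part]
    return train, independent


def assemble_binary_datasets(per_loc_train: dict, catalog: LocalizationCatalog | None = None):
    """Build the 9 one-vs-rest datasets from per-localization training lists."""
    if catalog is None:
        catalog = LocalizationCatalog()
    if len(catalog) < 2:
        raise ValueError("catalog needs at least 2 localizations to form negatives")
    missing = [n for n in catalog.names if not per_loc_train.get(n)]
    if missing:
        raise ValueError(f"localizations with zero positives: {missing}")
    datasets = []
    for name in catalog.names:
        positives = list(per_loc_train[name])
        negatives = [
            rec
            for other in catalog.names
            if other != name
            for rec in per_loc_train[other]
        ]
        datasets.append(BinaryDataset(name, positives, negatives))
    return datasets
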