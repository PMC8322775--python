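"""Readers and writers for the package's on-disk formats.

The canonical in-memory containers are small dataclasses around numpy
arrays: :class:`InteractionMatrix` (the binary lncRNA x protein matrix
``Y``), :class:`SequenceSet` (FASTA records over a declared alphabet) and
:class:`ExpressionProfileSet` (lncRNA expression across samples).  All
tabular formats are plain TSV so that fixtures and cached kernels stay
human-readable and diffable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: default mapping for ambiguous / non-standard amino-acid codes
AMBIGUOUS_AA_MAP = {"B": "N", "Z": "Q", "X": "A", "U": "C", "O": "K", "J": "L"}


@dataclass
class InteractionMatrix:
    """Binary interaction matrix ``Y`` with row (lncRNA) and column
    (protein) identifiers.

    Every entry is 0 or 1; identifiers are unique within each axis.
    """

    lncrna_ids: list[str]
    protein_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lncrna_ids = [str(i).strip() for i in self.lncrna_ids]
        self.protein_ids = [str(j).strip() for j in self.protein_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("interaction values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("interaction matrix must be at least 1x1")
        if len(self.lncrna_ids) != n or len(self.protein_ids) != m:
            raise ValueError("id lengths do not match matrix shape")
        if len(set(self.lncrna_ids)) != n:
            raise ValueError("duplicate lncRNA ids")
        if len(set(self.protein_ids)) != m:
            raise ValueError("duplicate protein ids")
        if not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.lncrna_ids, columns=self.protein_ids
        )


@dataclass
class SequenceSet:
    """Named sequences over a declared alphabet (``"rna"`` or ``"protein"``)."""

    ids: list[str]
    sequences: list[str]
    alphabet: str = "rna"

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        for sid, seq in zip(self.ids, self.sequences):
            if not seq:
                raise ValueError(f"empty sequence for id {sid!r}")

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, ids: list[str]) -> "SequenceSet":
        lookup = dict(zip(self.ids, self.sequences))
        missing = [i for i in ids if i not in lookup]
        if missing:
            raise KeyError(f"ids without sequence records: {missing}")
        return SequenceSet(list(ids), [lookup[i] for i in ids], self.alphabet)


@dataclass
class ExpressionProfileSet:
    """Per-lncRNA expression vectors of equal length across >= 2 samples."""

    lncrna_ids: list[str]
    profiles: np.ndarray
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 2:
            raise ValueError("profiles must form a 2-D matrix")
        if self.profiles.shape[1] < 2:
            raise ValueError("need at least 2 sample columns")
        if len(self.lncrna_ids) != self.profiles.shape[0]:
            raise ValueError("id count does not match profile rows")
        if not np.isfinite(self.profiles).all():
            raise ValueError("profiles contain missing or non-finite values")
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.profiles.shape[1])]

    def align_to(self, lncrna_ids: list[str]) -> "ExpressionProfileSet":
        """Restrict/reorder profiles to ``lncrna_ids``; ids present here but
        absent from the target are dropped with a warning."""
        index = {lid: i for i, lid in enumerate(self.lncrna_ids)}
        extra = [lid for lid in self.lncrna_ids if lid not in set(lncrna_ids)]
        if extra:
            logger.warning(
                "dropping %d expression profiles without interaction rows", len(extra)
            )
        missing = [lid for lid in lncrna_ids if lid not in index]
        if missing:
            raise KeyError(f"lncRNAs without expression profiles: {missing}")
        rows = [index[lid] for lid in lncrna_ids]
        return ExpressionProfileSet(
            list(lncrna_ids), self.profiles[rows], list(self.sample_ids)
        )


def read_interactions(path: str | Path, dialect: str = "triplet") -> InteractionMatrix:
    """Load a binary interaction matrix from a TSV file.

    ``triplet`` files carry one pair per line (``lncrna_id  protein_id
    [label]``, a missing third column meaning label 1); pairs absent from
    the file are 0.  ``dense`` files carry a header row of protein ids and
    one row per lncRNA.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "triplet":
        df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
        if df.shape[1] not in (2, 3):
            raise ValueError("triplet file must have 2 or 3 columns")
        if df.shape[1] == 2:
            df[2] = "1"
        df[2] = pd.to_numeric(df[2])
        if not df[2].isin([0, 1]).all():
            raise ValueError("triplet labels must be 0 or 1")
        df[0] = df[0].str.strip()
        df[1] = df[1].str.strip()
        conflicts = df.groupby([0, 1])[2].nunique()
        if (conflicts > 1).any():
            bad = conflicts[conflicts > 1].index.tolist()
            raise ValueError(f"conflicting duplicate pairs: {bad}")
        df = df.drop_duplicates([0, 1])
        lncrna_ids = sorted(df[0].unique())
        protein_ids = sorted(df[1].unique())
        li = {v: i for i, v in enumerate(lncrna_ids)}
        pi = {v: i for i, v in enumerate(protein_ids)}
        values = np.zeros((len(lncrna_ids), len(protein_ids)))
        for lid, pid, lab in df.itertuples(index=False):
            values[li[lid], pi[pid]] = lab
        return InteractionMatrix(lncrna_ids, protein_ids, values)
    if dialect == "dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.empty:
            raise ValueError("empty interaction matrix")
        return InteractionMatrix(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
        )
    raise ValueError(f"unknown dialect {dialect!r}")


def write_interactions(
    interactions: InteractionMatrix, path: str | Path, dialect: str = "dense"
) -> None:
    path = Path(path)
    if dialect == "dense":
        df = interactions.to_frame().astype(int)
        df.to_csv(path, sep="\t")
    elif dialect == "triplet":
        rows, cols = np.nonzero(interactions.values)
        with open(path, "w") as fh:
            for i, j in zip(rows, cols):
                fh.write(
                    f"{interactions.lncrna_ids[i]}\t{interactions.protein_ids[j]}\t1\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_fasta(
    path: str | Path, alphabet: str = "rna", policy: str = "strict"
) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Ids are taken from headers up to the first whitespace; sequences are
    uppercased; ``T`` is mapped to ``U`` under the RNA alphabet.  Under the
    default ``strict`` policy characters outside the alphabet are an error;
    for proteins the ``map`` policy rewrites ambiguity codes through
    :data:`AMBIGUOUS_AA_MAP`.
    """
    path = Path(path)
    ids: list[str] = []
    seqs: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        sid = record.id.strip()
        if sid in ids:
            raise ValueError(f"duplicate FASTA id {sid!r}")
        seq = str(record.seq).upper()
        if alphabet == "rna":
            seq = seq.replace("T", "U")
            legal = set(RNA_ALPHABET)
        elif alphabet == "protein":
            if policy == "map":
                seq = "".join(AMBIGUOUS_AA_MAP.get(c, c) for c in seq)
            legal = set(PROTEIN_ALPHABET) | (
                set(AMBIGUOUS_AA_MAP) if policy != "strict" else set()
            )
        else:
            raise ValueError(f"unknown alphabet {alphabet!r}")
        bad = set(seq) - legal
        if bad:
            if policy == "strict":
                raise ValueError(f"illegal characters {sorted(bad)} in {sid!r}")
            seq = "".join(c for c in seq if c in legal)
            logger.warning("dropped illegal characters %s from %r", sorted(bad), sid)
        ids.append(sid)
        seqs.append(seq)
    if not ids:
        raise ValueError(f"no FASTA records in {path}")
    return SequenceSet(ids, seqs, alphabet)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(seqs.ids, seqs.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")
    del width  # Biopython wraps at 60 columns; kept for signature stability


def read_expression(path: str | Path) -> ExpressionProfileSet:
    """Read a samples table: first column lncRNA id, remaining columns numeric."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise ValueError("expression table needs at least 2 sample columns")
    values = df.apply(pd.to_numeric).to_numpy(dtype=float)
    return ExpressionProfileSet(
        [str(i) for i in df.index], values, [str(c) for c in df.columns]
    )


def write_expression(profiles: ExpressionProfileSet, path: str | Path) -> None:
    pd.DataFrame(
        profiles.profiles, index=profiles.lncrna_ids, columns=profiles.sample_ids
    ).to_csv(path, sep="\t", float_format="%.12g")


def write_scores(
    scores: np.ndarray,
    lncrna_ids: list[str],
    protein_ids: list[str],
    path: str | Path,
) -> None:
    """Write a dense score matrix as TSV with ids; round-trips to 12
    significant digits."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(lncrna_ids), len(protein_ids)):
        raise ValueError("score matrix shape does not match ids")
    pd.DataFrame(scores, index=lncrna_ids, columns=protein_ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )


def read_scores(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    return (
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
    )


def read_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a cached square matrix (kernel/Laplacian) with shared row/col ids."""
    df = pd.read_csv(Path(path), sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(i) for i in df.index]


def write_matrix(matrix: np.ndarray, ids: list[str], path: str | Path) -> None:
    pd.DataFrame(matrix, index=ids, columns=ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )
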