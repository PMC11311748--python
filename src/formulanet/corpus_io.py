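"""Read, validate and represent tokenized prescription corpora.

A corpus is a list of prescriptions, each holding a set of herb tokens and a
set of indication tokens, plus a registry of tokens. The canonical exchange
format is a long (tidy) table with one row per prescription-token pair:

    prescription_id  token_id  token_kind  [prescription_name]  [token_name]

Binary incidence matrices (prescriptions x tokens of one kind) are derived
views; row order is the corpus order and fixes row order everywhere
downstream (distance matrices, embeddings, assignments).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

from formulanet.errors import (
    CorpusConsistencyError,
    CorpusFormatError,
    CorpusValidationError,
    EmptyInputError,
)

logger = logging.getLogger(__name__)

HERB = "herb"
INDICATION = "indication"
TOKEN_KINDS = (HERB, INDICATION)

TokenKind = Literal["herb", "indication"]

REQUIRED_COLUMNS = ("prescription_id", "token_id", "token_kind")
OPTIONAL_COLUMNS = ("prescription_name", "token_name")


@dataclass(frozen=True)
class Token:
    """A standardized semantic unit: one herb (H-ids) or one indication (S-ids).

    The H-/S- prefix convention is cosmetic; ids are treated as opaque strings.
    """

    token_id: str
    kind: TokenKind
    name: str = ""


@dataclass(frozen=True)
class Prescription:
    """One formula: its herb token set and indication token set.

    Herb sets are non-empty by corpus invariant (herb vectors drive all
    clustering); indication sets may be empty.
    """

    prescription_id: str
    herbs: frozenset
    indications: frozenset
    name: str = ""


@dataclass
class PrescriptionCorpus:
    """Ordered prescriptions plus the token registry.

    The prescription order is stable and defines matrix row order everywhere
    downstream; the token registry order defines column order.
    """

    prescriptions: list = field(default_factory=list)
    tokens: dict = field(default_factory=dict)  # token_id -> Token, ordered

    def __post_init__(self):
        self.validate()

    # -- basic access -----------------------------------------------------

    @property
    def ids(self) -> list:
        return [p.prescription_id for p in self.prescriptions]

    def token_ids(self, kind: TokenKind) -> list:
        return [t.token_id for t in self.tokens.values() if t.kind == kind]

    def __len__(self) -> int:
        return len(self.prescriptions)

    def __getitem__(self, prescription_id: str) -> Prescription:
        for p in self.prescriptions:
            if p.prescription_id == prescription_id:
                return p
        raise KeyError(prescription_id)

    def subset(self, member_ids: Iterable[str]) -> "PrescriptionCorpus":
        """Corpus restricted to the given prescriptions (corpus order kept)."""
        members = set(member_ids)
        unknown = members - set(self.ids)
        if unknown:
            raise KeyError(f"unknown prescription ids: {sorted(unknown)}")
        kept = [p for p in self.prescriptions if p.prescription_id in members]
        used = set().union(*(p.herbs | p.indications for p in kept)) if kept else set()
        tokens = {tid: t for tid, t in self.tokens.items() if tid in used}
        return PrescriptionCorpus(kept, tokens)

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        seen = set()
        for p in self.prescriptions:
            if p.prescription_id in seen:
                raise CorpusValidationError(
                    f"duplicate prescription_id {p.prescription_id!r}"
                )
            seen.add(p.prescription_id)
            if not p.herbs:
                raise CorpusValidationError(
                    f"prescription {p.prescription_id!r} has no herb tokens; "
                    "herb vectors drive all clustering"
                )
            if not p.indications:
                logger.warning(
                    "prescription %s has no indications; it contributes no "
                    "herb-indication edges",
                    p.prescription_id,
                )
            for tid in p.herbs:
                self._check_kind(tid, HERB, p.prescription_id)
            for tid in p.indications:
                self._check_kind(tid, INDICATION, p.prescription_id)

    def _check_kind(self, token_id: str, kind: str, pid: str) -> None:
        tok = self.tokens.get(token_id)
        if tok is None:
            raise CorpusConsistencyError(
                f"prescription {pid!r} references unregistered token {token_id!r}"
            )
        if tok.kind != kind:
            raise CorpusConsistencyError(
                f"token {token_id!r} registered as {tok.kind} but used as {kind} "
                f"in prescription {pid!r}"
            )


@dataclass
class IncidenceMatrix:
    """Binary prescriptions x tokens matrix for one token kind."""

    kind: TokenKind
    table: pd.DataFrame  # index = prescription ids, columns = token ids, 0/1

    @property
    def ids(self) -> list:
        return list(self.table.index)

    @property
    def token_ids(self) -> list:
        return list(self.table.columns)

    @property
    def values(self):
        return self.table.to_numpy()

    def token_sets(self) -> dict:
        """Reconstruct per-prescription token sets (round-trip of to_incidence)."""
        cols = self.table.columns.to_numpy()
        return {
            pid: frozenset(cols[row.to_numpy().astype(bool)])
            for pid, row in self.table.iterrows()
        }


# -- construction ---------------------------------------------------------


def corpus_from_records(
    records: Iterable[tuple],
    prescription_names: Mapping[str, str] | None = None,
    token_names: Mapping[str, str] | None = None,
) -> PrescriptionCorpus:
    """Build a corpus from (prescription_id, token_id, token_kind) triples.

    Duplicate triples collapse (set semantics); first-appearance order of
    prescriptions and tokens is preserved.
    """
    prescription_names = prescription_names or {}
    token_names = token_names or {}
    herb_sets: dict = {}
    ind_sets: dict = {}
    tokens: dict = {}
    for pid, tid, kind in records:
        pid, tid, kind = str(pid), str(tid), str(kind).strip().lower()
        if kind not in TOKEN_KINDS:
            raise CorpusFormatError(
                f"token_kind must be one of {TOKEN_KINDS}, got {kind!r}"
            )
        prior = tokens.get(tid)
        if prior is not None and prior.kind != kind:
            raise CorpusConsistencyError(
                f"token {tid!r} appears with kind={prior.kind} and kind={kind}"
            )
        if prior is None:
            tokens[tid] = Token(tid, kind, token_names.get(tid, ""))
        if pid not in herb_sets:
            herb_sets[pid] = set()
            ind_sets[pid] = set()
        (herb_sets if kind == HERB else ind_sets)[pid].add(tid)
    prescriptions = [
        Prescription(
            pid,
            frozenset(herb_sets[pid]),
            frozenset(ind_sets[pid]),
            prescription_names.get(pid, ""),
        )
        for pid in herb_sets
    ]
    return PrescriptionCorpus(prescriptions, tokens)


def read_corpus(path, delimiter: str | None = None) -> PrescriptionCorpus:
    """Read a long-format corpus table (CSV/TSV, UTF-8).

    Required columns: prescription_id, token_id, token_kind. Optional:
    prescription_name, token_name. Any dosage column is ignored with a
    warning (dosage is excluded from this analysis). Delimiter is
    auto-detected unless given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if delimiter is None:
            df = pd.read_csv(path, sep=None, engine="python", dtype=str, encoding="utf-8")
        else:
            df = pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8")
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"{path} is empty") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing required columns {missing}")
    dosage_cols = [c for c in df.columns if "dosage" in c.lower() or "dose" in c.lower()]
    if dosage_cols:
        logger.warning("ignoring dosage columns %s (dosage excluded from analysis)", dosage_cols)
    pnames = {}
    tnames = {}
    if "prescription_name" in df.columns:
        for pid, name in zip(df["prescription_id"], df["prescription_name"]):
            if pd.notna(name) and str(pid) not in pnames:
                pnames[str(pid)] = str(name)
    if "token_name" in df.columns:
        for tid, name in zip(df["token_id"], df["token_name"]):
            if pd.notna(name) and str(tid) not in tnames:
                tnames[str(tid)] = str(name)
    records = zip(df["prescription_id"], df["token_id"], df["token_kind"])
    return corpus_from_records(records, pnames, tnames)


def write_corpus(corpus: PrescriptionCorpus, path, delimiter: str = "\t") -> None:
    """Write the long-format table; read_corpus(write_corpus(c)) == c."""
    rows = []
    for p in corpus.prescriptions:
        # registry order within each prescription keeps output deterministic
        for tid in corpus.tokens:
            if tid in p.herbs or tid in p.indications:
                tok = corpus.tokens[tid]
                rows.append(
                    (p.prescription_id, tid, tok.kind, p.name, tok.name)
                )
    df = pd.DataFrame(
        rows,
        columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS[:1]) + ["token_name"],
    )
    df.columns = ["prescription_id", "token_id", "token_kind", "prescription_name", "token_name"]
    df.to_csv(path, sep=delimiter, index=False, encoding="utf-8")


def read_wide_matrix(path, kind: TokenKind, delimiter: str | None = None) -> PrescriptionCorpus:
    """Convenience reader for a wide binary matrix (rows = prescriptions).

    First column holds prescription ids; remaining columns are token ids of
    a single kind. Intended for herb matrices; a herbless corpus is invalid.
    """
    if delimiter is None:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    else:
        df = pd.read_csv(path, sep=delimiter, index_col=0)
    bad = ~df.isin([0, 1]).all()
    if bad.any():
        raise CorpusFormatError(
            f"non-binary entries in columns {list(df.columns[bad])}"
        )
    records = [
        (pid, tid, kind)
        for pid, row in df.iterrows()
        for tid, v in row.items()
        if int(v) == 1
    ]
    return corpus_from_records(records)


# -- derived views --------------------------------------------------------


def to_incidence(corpus: PrescriptionCorpus, kind: TokenKind) -> IncidenceMatrix:
    """Binary incidence matrix: entry (i, j) = 1 iff prescription i contains token j.

    Rows follow corpus order, columns follow token-registry order.
    """
    if kind not in TOKEN_KINDS:
        raise ValueError(f"kind must be one of {TOKEN_KINDS}, got {kind!r}")
    if len(corpus) == 0:
        raise EmptyInputError("cannot build an incidence matrix from an empty corpus")
    cols = corpus.token_ids(kind)
    data = [
        [1 if tid in (p.herbs if kind == HERB else p.indications) else 0 for tid in cols]
        for p in corpus.prescriptions
    ]
    table = pd.DataFrame(data, index=corpus.ids, columns=cols, dtype="int8")
    return IncidenceMatrix(kind=kind, table=table)


def corpus_summary(corpus: PrescriptionCorpus) -> dict:
    """Corpus-level counts and per-token frequencies.

    Frequency of a token = number of prescriptions containing it, the
    quantity that sizes nodes in the herb-indication network.
    """
    herb_freq = {tid: 0 for tid in corpus.token_ids(HERB)}
    ind_freq = {tid: 0 for tid in corpus.token_ids(INDICATION)}
    for p in corpus.prescriptions:
        for tid in p.herbs:
            herb_freq[tid] += 1
        for tid in p.indications:
            ind_freq[tid] += 1
    return {
        "n_prescriptions": len(corpus),
        "n_herbs": len(herb_freq),
        "n_indications": len(ind_freq),
        "herb_frequency": herb_freq,
        "indication_frequency": ind_freq,
    }


def write_summary(corpus: PrescriptionCorpus, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(corpus_summary(corpus), fh, indent=2, sort_keys=False)
        fh.write("\n")
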