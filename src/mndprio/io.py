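"""CSV readers/writers, drug-name normalisation and corpus validation.

File formats (UTF-8, comma-separated, mandatory header row):

* ``publications.csv``: pub_id,drug,disease,year,design,n_participants,safety_category,primary_outcome_id
* ``outcomes.csv``: pub_id,outcome_id,efficacy_category
* ``quality.csv``: pub_id,item_id,response
* ``preclinical.csv``: study_id,drug,species_model,n_animals,median_survival_treated,median_survival_control
* ``synonyms.csv``: variant,canonical

A missing ``primary_outcome_id`` is written as an empty field.  Drug names
are normalised against a synonym table at load time; matching is
case-insensitive after whitespace and hyphen normalisation, so e.g.
"acetylcysteine", "N-acetylcysteine" and "N-acetyl cystine" all map to the
canonical "N-acetyl cysteine".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .records import (
    DESIGNS,
    DISEASES,
    EFFICACY_CATEGORIES,
    OUTCOME_COLUMNS,
    PRECLINICAL_COLUMNS,
    PUBLICATION_COLUMNS,
    QUALITY_COLUMNS,
    SAFETY_CATEGORIES,
    Corpus,
)
from .registry import checklist_items, is_legal_response

__all__ = [
    "SynonymTable",
    "ValidationIssue",
    "CorpusLoadError",
    "normalize_drug_name",
    "load_corpus",
    "write_corpus",
    "validate_corpus",
]


class CorpusLoadError(ValueError):
    """Raised when a corpus file violates its schema or referential integrity."""


def _canonical_spacing(name: str) -> str:
    """Trim and collapse internal whitespace; case is otherwise preserved."""
    return re.sub(r"\s+", " ", name.strip())


def _fold(name: str) -> str:
    """Matching key: lower-case with all whitespace and hyphens removed."""
    return re.sub(r"[\s\-]+", "", name.strip().lower())


@dataclass
class SynonymTable:
    """Mapping from drug-name variants to canonical names.

    Canonical names are fixed points: looking up a canonical name returns
    itself.  An empty table leaves every name unmatched.
    """

    mapping: dict[str, str] = field(default_factory=dict)  # fold(variant) -> canonical

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]] | Mapping[str, str]) -> "SynonymTable":
        if isinstance(pairs, Mapping):
            pairs = pairs.items()
        mapping: dict[str, str] = {}
        for variant, canonical in pairs:
            canonical = _canonical_spacing(canonical)
            mapping[_fold(variant)] = canonical
            mapping.setdefault(_fold(canonical), canonical)
        return cls(mapping)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SynonymTable":
        df = pd.read_csv(path, dtype=str).fillna("")
        missing = {"variant", "canonical"} - set(df.columns)
        if missing:
            raise CorpusLoadError(f"{path}: missing columns {sorted(missing)}")
        return cls.from_pairs(zip(df["variant"], df["canonical"]))

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.mapping.items())
        return pd.DataFrame(rows, columns=["variant", "canonical"])


def normalize_drug_name(name: str, synonyms: SynonymTable | None = None) -> tuple[str, bool]:
    """Resolve a drug name against a synonym table.

    Returns ``(canonical_name, True)`` when a synonym matches
    (case/whitespace/hyphen-insensitively); otherwise the trimmed,
    whitespace-collapsed input with ``matched=False``.  Idempotent: the
    canonical name maps to itself.

    Raises
    ------
    ValueError
        If ``name`` is empty or whitespace-only.
    """
    if not name or not name.strip():
        raise ValueError("drug name must be non-empty")
    if synonyms is not None:
        canonical = synonyms.mapping.get(_fold(name))
        if canonical is not None:
            return canonical, True
    return _canonical_spacing(name), False


@dataclass(frozen=True)
class ValidationIssue:
    """One invariant violation: the offending record, table and rule."""

    table: str
    record_id: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.table}] {self.record_id}: {self.rule}"


_ENUMS = {
    ("publications", "disease"): DISEASES,
    ("publications", "design"): DESIGNS,
    ("publications", "safety_category"): SAFETY_CATEGORIES,
    ("outcomes", "efficacy_category"): EFFICACY_CATEGORIES,
}

_FILES = {
    "publications": PUBLICATION_COLUMNS,
    "outcomes": OUTCOME_COLUMNS,
    "quality": QUALITY_COLUMNS,
    "preclinical": PRECLINICAL_COLUMNS,
}


def _read_table(path: Path, name: str) -> pd.DataFrame:
    expected = _FILES[name]
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise CorpusLoadError(f"{path}: file not found") from None
    missing = set(expected) - set(df.columns)
    if missing:
        raise CorpusLoadError(f"{path}: missing columns {sorted(missing)}")
    df = df[list(expected)]
    # enum checks with file/row/column in the message
    for (table, col), tokens in _ENUMS.items():
        if table != name:
            continue
        bad = ~df[col].isin(tokens)
        if bad.any():
            row = int(df.index[bad][0])
            raise CorpusLoadError(
                f"{path} row {row + 2} column '{col}': "
                f"unknown token {df.loc[df.index[bad][0], col]!r}"
            )
    return df


def _to_int(df: pd.DataFrame, col: str, path: Path, minimum: int | None = None) -> pd.DataFrame:
    try:
        values = pd.to_numeric(df[col])
    except (ValueError, TypeError) as exc:
        raise CorpusLoadError(f"{path} column '{col}': non-numeric value ({exc})") from None
    if minimum is not None and (values < minimum).any():
        row = int(df.index[values < minimum][0])
        raise CorpusLoadError(f"{path} row {row + 2} column '{col}': value below {minimum}")
    df = df.copy()
    df[col] = values
    return df


def load_corpus(
    directory: str | Path,
    synonyms: SynonymTable | None = None,
    strict: bool = True,
) -> Corpus:
    """Load a corpus from a directory of CSV files.

    Drug fields are normalised against ``synonyms`` (when given, or against
    ``synonyms.csv`` in the directory if present).  With ``strict=True``
    (default) any invariant violation raises :class:`CorpusLoadError`; with
    ``strict=False`` the corpus is returned and issues are left to
    :func:`validate_corpus`.
    """
    directory = Path(directory)
    if synonyms is None:
        syn_path = directory / "synonyms.csv"
        synonyms = SynonymTable.from_csv(syn_path) if syn_path.exists() else SynonymTable()

    pubs = _read_table(directory / "publications.csv", "publications")
    outcomes = _read_table(directory / "outcomes.csv", "outcomes")
    quality = _read_table(directory / "quality.csv", "quality")
    preclinical = _read_table(directory / "preclinical.csv", "preclinical")

    pubs = _to_int(pubs, "year", directory / "publications.csv")
    pubs = _to_int(pubs, "n_participants", directory / "publications.csv", minimum=1)
    preclinical = _to_int(preclinical, "n_animals", directory / "preclinical.csv", minimum=1)
    for col in ("median_survival_treated", "median_survival_control"):
        preclinical = preclinical.copy()
        preclinical[col] = pd.to_numeric(preclinical[col])
        if (preclinical[col] <= 0).any():
            raise CorpusLoadError(
                f"{directory / 'preclinical.csv'} column '{col}': non-positive median"
            )

    for df in (pubs, preclinical):
        df["drug"] = [normalize_drug_name(d, synonyms)[0] for d in df["drug"]]
    pubs["primary_outcome_id"] = pubs["primary_outcome_id"].replace("", pd.NA)

    corpus = Corpus(publications=pubs, outcomes=outcomes, quality=quality, preclinical=preclinical)
    if strict:
        issues = validate_corpus(corpus)
        if issues:
            raise CorpusLoadError(
                f"{directory}: corpus failed validation:\n"
                + "\n".join(str(i) for i in issues)
            )
    return corpus


def write_corpus(corpus: Corpus, directory: str | Path) -> dict[str, Path]:
    """Write the four corpus tables (and nothing else) as CSV files.

    Output is bit-stable: re-loading the written files yields an equal
    corpus, and writing the same corpus twice yields identical bytes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    tables = {
        "publications": corpus.publications,
        "outcomes": corpus.outcomes,
        "quality": corpus.quality,
        "preclinical": corpus.preclinical,
    }
    for name, df in tables.items():
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        paths[name] = path
    return paths


def validate_corpus(corpus: Corpus) -> list[ValidationIssue]:
    """Check every type invariant; report issues, never raise.

    Returns an empty list iff the corpus is valid.  Checks: unique ids,
    enum membership, positive counts and medians, legal checklist
    responses, at most one response per (pub_id, item_id), and referential
    integrity of outcomes, quality responses and primary-outcome links.
    """
    issues: list[ValidationIssue] = []
    pubs, outs, qual, pre = (
        corpus.publications,
        corpus.outcomes,
        corpus.quality,
        corpus.preclinical,
    )

    for pid in pubs.loc[pubs["pub_id"].duplicated(), "pub_id"].unique():
        issues.append(ValidationIssue("publications", str(pid), "duplicate pub_id"))
    for sid in pre.loc[pre["study_id"].duplicated(), "study_id"].unique():
        issues.append(ValidationIssue("preclinical", str(sid), "duplicate study_id"))

    for (table, col), tokens in _ENUMS.items():
        df = getattr(corpus, table)
        for _, row in df.loc[~df[col].isin(tokens)].iterrows():
            rid = row.get("pub_id", row.get("study_id", "?"))
            issues.append(
                ValidationIssue(table, str(rid), f"illegal {col} value {row[col]!r}")
            )

    if len(pubs) and (pd.to_numeric(pubs["n_participants"], errors="coerce") < 1).any():
        for _, row in pubs.loc[
            pd.to_numeric(pubs["n_participants"], errors="coerce") < 1
        ].iterrows():
            issues.append(ValidationIssue("publications", row["pub_id"], "n_participants < 1"))

    pub_ids = set(pubs["pub_id"])
    for _, row in outs.loc[~outs["pub_id"].isin(pub_ids)].iterrows():
        issues.append(
            ValidationIssue("outcomes", row["pub_id"], "references absent publication")
        )
    dup = outs.duplicated(subset=["pub_id", "outcome_id"])
    for _, row in outs.loc[dup].iterrows():
        issues.append(
            ValidationIssue(
                "outcomes", f"{row['pub_id']}/{row['outcome_id']}", "duplicate outcome"
            )
        )

    # primary outcome link
    if len(pubs):
        flagged = pubs.dropna(subset=["primary_outcome_id"])
        keys = set(zip(outs["pub_id"], outs["outcome_id"]))
        for _, row in flagged.iterrows():
            if (row["pub_id"], row["primary_outcome_id"]) not in keys:
                issues.append(
                    ValidationIssue(
                        "publications",
                        row["pub_id"],
                        f"primary_outcome_id {row['primary_outcome_id']!r} has no outcome record",
                    )
                )

    registry = checklist_items()
    for _, row in qual.iterrows():
        if row["pub_id"] not in pub_ids:
            issues.append(
                ValidationIssue("quality", row["pub_id"], "references absent publication")
            )
        if row["item_id"] not in registry:
            issues.append(
                ValidationIssue("quality", row["pub_id"], f"unknown item {row['item_id']!r}")
            )
        elif not is_legal_response(row["item_id"], row["response"]):
            issues.append(
                ValidationIssue(
                    "quality",
                    row["pub_id"],
                    f"response {row['response']!r} illegal for "
                    f"{registry[row['item_id']].response_class} item {row['item_id']!r}",
                )
            )
    dup = qual.duplicated(subset=["pub_id", "item_id"])
    for _, row in qual.loc[dup].iterrows():
        issues.append(
            ValidationIssue(
                "quality", f"{row['pub_id']}/{row['item_id']}", "duplicate checklist response"
            )
        )

    if len(pre):
        for col in ("median_survival_treated", "median_survival_control"):
            bad = pd.to_numeric(pre[col], errors="coerce") <= 0
            for _, row in pre.loc[bad].iterrows():
                issues.append(
                    ValidationIssue("preclinical", row["study_id"], f"non-positive {col}")
                )
        bad = pd.to_numeric(pre["n_animals"], errors="coerce") < 1
        for _, row in pre.loc[bad].iterrows():
            issues.append(ValidationIssue("preclinical", row["study_id"], "n_animals < 1"))

    return issues
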