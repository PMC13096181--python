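"""Bibliographic corpus engine.

Turns raw bibliographic exports (Web-of-Science / Scopus style tabular
records) into deduplicated documents and genus-by-year publication counts.
The chain is:

1. per-source cleaning and deduplication (:func:`normalize_doi`,
   :func:`dedup_within_source`);
2. precision-first cross-source record linkage — exact merge on normalised
   DOI, then greedy one-to-one title matching within publication year
   (:func:`match_cross_source`);
3. an alias library per genus (canonical name, auto-generated binomial
   abbreviations such as "a. mellifera", configured common names), every
   alias stored Porter-stemmed (:func:`build_alias_library`);
4. a Porter-stemmed positional inverted index over title+abstract text
   (:class:`InvertedIndex`) and phrase-based mention counting in which a
   document contributes at most one count per genus
   (:func:`count_genus_mentions`);
5. a validation harness comparing automated totals against manual
   reference counts (:func:`validate_counts`).

Ambiguity handling is conservative: multi-token aliases must match as
*consecutive* stemmed tokens, abbreviation aliases shared by two genera are
dropped with a warning, and ``mode="high_confidence"`` excludes
abbreviation aliases entirely.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.proportion import proportion_confint

from .porter import stem

UNKNOWN_YEAR = -1

_SOURCES = ("wos", "scopus")
_ALIAS_DELIMITERS = re.compile(r"[;,/|]")
_TOKEN_RE = re.compile(r"[a-z0-9]+")


# ---------------------------------------------------------------------------
# records and document linkage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SourceRecord:
    """One raw export row (UT/EID-keyed) from a single bibliographic source."""

    record_id: str
    source: str
    doi: str | None = None
    title: str = ""
    abstract: str = ""
    year: int | None = None
    doc_type: str = ""
    language: str = ""
    country_text: str = ""

    def __post_init__(self):
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if self.source not in _SOURCES:
            raise ValueError(f"source must be one of {_SOURCES}, got {self.source!r}")
        if self.year is not None and not (1900 <= self.year <= 2100):
            raise ValueError(f"year {self.year} outside [1900, 2100]")


@dataclass(frozen=True)
class UnifiedDocument:
    """A document after cross-source linkage."""

    doc_id: str
    provenance: str  # "wos_only" | "scopus_only" | "both"
    year: int | None
    title: str
    abstract: str
    doi: str | None
    country_text: str = ""

    @property
    def text(self) -> str:
        return f"{self.title} {self.abstract}".strip()


@dataclass
class CrossSourceResult:
    intersection: list[UnifiedDocument]
    wos_only: list[UnifiedDocument]
    scopus_only: list[UnifiedDocument]

    @property
    def documents(self) -> list[UnifiedDocument]:
        return self.intersection + self.wos_only + self.scopus_only

    @property
    def union_size(self) -> int:
        return len(self.intersection) + len(self.wos_only) + len(self.scopus_only)


def normalize_doi(raw: str | None) -> str | None:
    """Lower-case, trim, strip a leading ``doi:`` prefix; empty -> None."""
    if raw is None:
        return None
    doi = raw.strip().lower()
    if doi.startswith("doi:"):
        doi = doi[4:].strip()
    return doi or None


def dedup_within_source(records: Sequence[SourceRecord]) -> list[SourceRecord]:
    """Keep the first record per native id, then the first per normalised DOI.

    Input order is preserved otherwise; null DOIs never collide. Idempotent.
    """
    sources = {r.source for r in records}
    if len(sources) > 1:
        raise ValueError(f"records mix source tags: {sorted(sources)}")
    out: list[SourceRecord] = []
    seen_ids: set[str] = set()
    seen_dois: set[str] = set()
    for r in records:
        if r.record_id in seen_ids:
            continue
        seen_ids.add(r.record_id)
        doi = normalize_doi(r.doi)
        if doi is not None:
            if doi in seen_dois:
                continue
            seen_dois.add(doi)
        out.append(r)
    return out


def _unify(record: SourceRecord, provenance: str, partner: SourceRecord | None = None) -> UnifiedDocument:
    if partner is None:
        doc_id = f"{record.source}:{record.record_id}"
        country = record.country_text
    else:
        doc_id = f"wos:{record.record_id}|scopus:{partner.record_id}"
        country = record.country_text or partner.country_text
    return UnifiedDocument(
        doc_id=doc_id,
        provenance=provenance,
        year=record.year,
        title=record.title,
        abstract=record.abstract or (partner.abstract if partner else ""),
        doi=normalize_doi(record.doi) or (normalize_doi(partner.doi) if partner else None),
        country_text=country,
    )


def title_similarity(a: str, b: str) -> float:
    """Token-set overlap ratio: |shared| / |smaller set| over word tokens."""
    ta = set(_TOKEN_RE.findall(a.lower()))
    tb = set(_TOKEN_RE.findall(b.lower()))
    if not ta or not tb:
        return 0.0
    return len(ta & tb) / min(len(ta), len(tb))


def match_cross_source(
    wos: Sequence[SourceRecord],
    scopus: Sequence[SourceRecord],
    sim_threshold: float = 0.9,
) -> CrossSourceResult:
    """Two-step precision-first linkage of two deduplicated record sets.

    Step 1 merges records sharing a normalised DOI. Step 2 groups the
    remainder by identical publication year and greedily links the pair with
    the highest token-overlap title similarity >= ``sim_threshold``; each
    record is linked at most once, ties broken by input order. The returned
    partition satisfies ``|union| = |intersection| + |wos_only| +
    |scopus_only|`` by construction.
    """
    if not (0 < sim_threshold <= 1):
        raise ValueError(f"sim_threshold must be in (0, 1], got {sim_threshold}")

    intersection: list[UnifiedDocument] = []
    matched_w: set[int] = set()
    matched_s: set[int] = set()

    by_doi: dict[str, int] = {}
    for j, r in enumerate(scopus):
        doi = normalize_doi(r.doi)
        if doi is not None and doi not in by_doi:
            by_doi[doi] = j
    for i, r in enumerate(wos):
        doi = normalize_doi(r.doi)
        if doi is not None and doi in by_doi:
            j = by_doi[doi]
            if j not in matched_s:
                intersection.append(_unify(r, "both", scopus[j]))
                matched_w.add(i)
                matched_s.add(j)

    w_by_year: dict[int | None, list[int]] = {}
    for i, r in enumerate(wos):
        if i not in matched_w:
            w_by_year.setdefault(r.year, []).append(i)
    s_by_year: dict[int | None, list[int]] = {}
    for j, r in enumerate(scopus):
        if j not in matched_s:
            s_by_year.setdefault(r.year, []).append(j)

    for year, w_idx in w_by_year.items():
        if year is None or year not in s_by_year:
            continue
        candidates = []
        for i in w_idx:
            for j in s_by_year[year]:
                sim = title_similarity(wos[i].title, scopus[j].title)
                if sim >= sim_threshold:
                    candidates.append((-sim, i, j))
        for _, i, j in sorted(candidates):
            if i in matched_w or j in matched_s:
                continue
            intersection.append(_unify(wos[i], "both", scopus[j]))
            matched_w.add(i)
            matched_s.add(j)

    wos_only = [_unify(r, "wos_only") for i, r in enumerate(wos) if i not in matched_w]
    scopus_only = [_unify(r, "scopus_only") for j, r in enumerate(scopus) if j not in matched_s]
    return CrossSourceResult(intersection, wos_only, scopus_only)


# ---------------------------------------------------------------------------
# tokenisation and alias library
# ---------------------------------------------------------------------------

def tokenize(text: str) -> list[str]:
    """Lower-case and split on non-alphanumeric characters."""
    return _TOKEN_RE.findall(text.lower())


def tokenize_and_stem(text: str) -> list[str]:
    """Lower-case, strip punctuation, Porter-stem each token."""
    return [stem(t) for t in tokenize(text)]


@dataclass(frozen=True)
class Alias:
    phrase: str
    stemmed: tuple[str, ...]
    kind: str  # "genus" | "abbreviation" | "common_name"


@dataclass
class GenusEntry:
    genus: str
    family: str = ""
    species_richness: int = 0
    managed: bool = False
    sociality: str = "solitary"  # "social" | "solitary"
    nesting: str = "ground"  # ground | cavity | wood_excavating | large_colony_cavity
    aliases: list[Alias] = field(default_factory=list)


@dataclass
class AliasLibrary:
    """Genus -> alias phrases (original and Porter-stemmed) plus attributes."""

    entries: dict[str, GenusEntry]

    @property
    def genera(self) -> list[str]:
        return list(self.entries)

    def aliases_for(self, genus: str, include_abbreviations: bool = True) -> list[Alias]:
        aliases = self.entries[genus].aliases
        if include_abbreviations:
            return list(aliases)
        return [a for a in aliases if a.kind != "abbreviation"]

    def attribute_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genus": e.genus,
                "family": e.family,
                "species_richness": e.species_richness,
                "managed": e.managed,
                "sociality": e.sociality,
                "nesting": e.nesting,
            }
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows)


DEFAULT_COMMON_NAMES: dict[str, str] = {
    "honey bee": "Apis",
    "honey bees": "Apis",
    "honeybee": "Apis",
    "honeybees": "Apis",
    "bumble bee": "Bombus",
    "bumble bees": "Bombus",
    "bumblebee": "Bombus",
    "bumblebees": "Bombus",
    "carpenter bee": "Xylocopa",
    "carpenter bees": "Xylocopa",
    "mason bee": "Osmia",
    "mason bees": "Osmia",
    "leafcutter bee": "Megachile",
    "leafcutter bees": "Megachile",
    "leaf-cutting bee": "Megachile",
    "leaf-cutting bees": "Megachile",
    "mining bee": "Andrena",
    "mining bees": "Andrena",
}


def _normalize_alias(phrase: str) -> str:
    return " ".join(phrase.lower().split())


def split_multivalued(cell: str) -> list[str]:
    """Split a multi-valued alias cell on ';', ',', '/', '|'."""
    return [p for p in (s.strip() for s in _ALIAS_DELIMITERS.split(cell)) if p]


def binomial_abbreviation(genus: str, species: str) -> str:
    """"Apis mellifera" (or epithet "mellifera") -> "a. mellifera"."""
    epithet = species.strip().lower().split()[-1]
    return f"{genus[0].lower()}. {epithet}"


def build_alias_library(
    genus_table: pd.DataFrame | Iterable[Mapping],
    common_names: Mapping[str, str] | None = None,
    species_names: Mapping[str, Sequence[str]] | None = None,
) -> AliasLibrary:
    """Build the per-genus alias library.

    ``genus_table`` needs one row per genus with (at least) a ``genus``
    column; ``family``, ``species_richness``, ``managed``, ``sociality``,
    ``nesting`` and an optional multi-valued ``aliases`` cell are carried
    through. ``common_names`` maps alias phrase -> genus (defaults to the
    curated honeybee/bumblebee/... expansions); ``species_names`` maps genus
    -> species names from which binomial abbreviations are generated.

    A non-abbreviation alias claimed by two genera raises; colliding
    abbreviations are dropped with a warning (conservative, since e.g. "A."
    could stand for several genera).
    """
    if isinstance(genus_table, pd.DataFrame):
        rows = genus_table.to_dict("records")
    else:
        rows = [dict(r) for r in genus_table]
    if common_names is None:
        common_names = DEFAULT_COMMON_NAMES

    entries: dict[str, GenusEntry] = {}
    for row in rows:
        genus = str(row["genus"]).strip().capitalize()
        if genus in entries:
            raise ValueError(f"duplicate genus row: {genus}")
        entries[genus] = GenusEntry(
            genus=genus,
            family=str(row.get("family", "") or ""),
            species_richness=int(row.get("species_richness", 0) or 0),
            managed=bool(row.get("managed", False)),
            sociality=str(row.get("sociality", "solitary") or "solitary"),
            nesting=str(row.get("nesting", "ground") or "ground"),
        )

    # phrase -> (genus, kind); collisions resolved per kind
    claimed: dict[str, tuple[str, str]] = {}
    dropped: set[str] = set()

    def claim(genus: str, phrase: str, kind: str) -> None:
        phrase = _normalize_alias(phrase)
        if not phrase:
            return
        if phrase in dropped:
            return
        prior = claimed.get(phrase)
        if prior is not None:
            if prior[0] == genus:
                return
            if kind == "abbreviation" and prior[1] == "abbreviation":
                warnings.warn(
                    f"abbreviation alias {phrase!r} is ambiguous "
                    f"({prior[0]} vs {genus}); dropped",
                    stacklevel=2,
                )
                dropped.add(phrase)
                del claimed[phrase]
                return
            raise ValueError(
                f"alias {phrase!r} maps to two genera: {prior[0]} and {genus}"
            )
        claimed[phrase] = (genus, kind)

    for row in rows:
        genus = str(row["genus"]).strip().capitalize()
        claim(genus, genus, "genus")
        for cell in (row.get("aliases"), row.get("common_names")):
            if cell and not (isinstance(cell, float) and np.isnan(cell)):
                for phrase in split_multivalued(str(cell)):
                    claim(genus, phrase, "common_name")
    for phrase, genus in common_names.items():
        if genus in entries:
            claim(genus, phrase, "common_name")
    if species_names:
        for genus, names in species_names.items():
            genus = genus.strip().capitalize()
            if genus not in entries:
                continue
            for sp in names:
                claim(genus, binomial_abbreviation(genus, sp), "abbreviation")

    for phrase, (genus, kind) in claimed.items():
        stemmed = tuple(tokenize_and_stem(phrase))
        if not stemmed:
            raise ValueError(f"alias {phrase!r} empty after normalisation")
        entries[genus].aliases.append(Alias(phrase, stemmed, kind))
    return AliasLibrary(entries)


# ---------------------------------------------------------------------------
# inverted index and counting
# ---------------------------------------------------------------------------

class InvertedIndex:
    """Stemmed token -> posting lists with positions, for phrase matching."""

    def __init__(self) -> None:
        self.postings: dict[str, dict[str, list[int]]] = {}
        self.doc_years: dict[str, int | None] = {}

    @classmethod
    def build(cls, docs: Iterable[UnifiedDocument]) -> "InvertedIndex":
        index = cls()
        for doc in docs:
            if doc.doc_id in index.doc_years:
                raise ValueError(f"duplicate doc_id: {doc.doc_id}")
            index.doc_years[doc.doc_id] = doc.year
            for pos, token in enumerate(tokenize_and_stem(doc.text)):
                index.postings.setdefault(token, {}).setdefault(doc.doc_id, []).append(pos)
        return index

    @property
    def n_docs(self) -> int:
        return len(self.doc_years)

    def lookup(self, token: str) -> frozenset[str]:
        return frozenset(self.postings.get(token, ()))

    def phrase_docs(self, phrase: tuple[str, ...]) -> set[str]:
        """Documents containing the stemmed tokens consecutively."""
        if not phrase:
            return set()
        candidates = self.lookup(phrase[0])
        for token in phrase[1:]:
            candidates = candidates & self.lookup(token)
            if not candidates:
                return set()
        if len(phrase) == 1:
            return set(candidates)
        hits = set()
        for doc_id in candidates:
            starts = self.postings[phrase[0]][doc_id]
            for p in starts:
                if all(p + k in self.postings[phrase[k]][doc_id] for k in range(1, len(phrase))):
                    hits.add(doc_id)
                    break
        return hits


@dataclass
class GenusYearCounts:
    """(genus, year) publication counts plus unordered genus co-occurrence."""

    counts: dict[tuple[str, int], int]
    cooccurrence: dict[tuple[str, str], int]
    doc_genera: dict[str, frozenset[str]]

    def total(self, genus: str) -> int:
        return sum(c for (g, _), c in self.counts.items() if g == genus)

    def totals(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (g, _), c in self.counts.items():
            out[g] = out.get(g, 0) + c
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [{"genus": g, "year": y, "count": c} for (g, y), c in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["genus", "year", "count"])

    def cooccurrence_frame(self) -> pd.DataFrame:
        rows = [
            {"genus_a": a, "genus_b": b, "count": c}
            for (a, b), c in sorted(self.cooccurrence.items())
        ]
        return pd.DataFrame(rows, columns=["genus_a", "genus_b", "count"])


def count_genus_mentions(
    index: InvertedIndex,
    library: AliasLibrary,
    mode: str = "full",
) -> GenusYearCounts:
    """Count documents mentioning each genus, once per document per genus.

    A document matches a genus iff any of the genus's alias phrases occurs as
    consecutive stemmed tokens. ``mode="high_confidence"`` restricts matching
    to full genus names and common names, excluding binomial-abbreviation
    aliases. Documents without a year are bucketed under ``UNKNOWN_YEAR``.
    """
    if mode not in ("full", "high_confidence"):
        raise ValueError(f"mode must be 'full' or 'high_confidence', got {mode!r}")
    include_abbrev = mode == "full"

    doc_genera: dict[str, set[str]] = {}
    for genus in library.genera:
        matched: set[str] = set()
        for alias in library.aliases_for(genus, include_abbreviations=include_abbrev):
            matched |= index.phrase_docs(alias.stemmed)
        for doc_id in matched:
            doc_genera.setdefault(doc_id, set()).add(genus)

    counts: dict[tuple[str, int], int] = {}
    cooc: dict[tuple[str, str], int] = {}
    for doc_id, genera in doc_genera.items():
        year = index.doc_years[doc_id]
        year = UNKNOWN_YEAR if year is None else year
        for g in genera:
            counts[(g, year)] = counts.get((g, year), 0) + 1
        ordered = sorted(genera)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1:]:
                cooc[(a, b)] = cooc.get((a, b), 0) + 1
    return GenusYearCounts(counts, cooc, {d: frozenset(g) for d, g in doc_genera.items()})


def match_countries(text: str, gazetteer: Mapping[str, str]) -> set[str]:
    """Exact whole-phrase, case-insensitive gazetteer matches -> ISO3 codes."""
    low = text.lower()
    hits: set[str] = set()
    for name, iso3 in gazetteer.items():
        pattern = r"(?<![a-z0-9])" + re.escape(name.lower()) + r"(?![a-z0-9])"
        if re.search(pattern, low):
            hits.add(iso3)
    return hits


# ---------------------------------------------------------------------------
# validation harness
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    """Agreement between automated and manual genus totals."""

    n_genera: int
    spearman_rho: float
    pearson_r: float
    mae: float
    rmse: float
    ols_slope: float
    ols_intercept: float
    r_squared: float
    precision: float | None = None
    precision_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "n_genera": self.n_genera,
            "spearman_rho": self.spearman_rho,
            "pearson_r": self.pearson_r,
            "mae": self.mae,
            "rmse": self.rmse,
            "ols_slope": self.ols_slope,
            "ols_intercept": self.ols_intercept,
            "r_squared": self.r_squared,
        }
        if self.precision is not None:
            d["precision"] = self.precision
            d["precision_ci"] = list(self.precision_ci)
        return d


def validate_counts(
    auto: Mapping[str, float],
    manual: Mapping[str, float],
    labelled_sample: tuple[int, int] | None = None,
) -> ValidationReport:
    """Compare automated against manual reference counts over shared genera.

    Reports Spearman rho (average ranks on ties), Pearson r, MAE, RMSE and
    the OLS slope/intercept of manual on automated. ``labelled_sample`` is an
    optional ``(n_correct, n_labelled)`` pair from a manual precision audit,
    reported with a Wilson score interval.
    """
    shared = sorted(set(auto) & set(manual))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genera, got {len(shared)}")
    a = np.asarray([auto[g] for g in shared], dtype=float)
    m = np.asarray([manual[g] for g in shared], dtype=float)

    rho = sps.spearmanr(a, m).statistic
    r = sps.pearsonr(a, m).statistic
    mae = float(np.mean(np.abs(a - m)))
    rmse = float(np.sqrt(np.mean((a - m) ** 2)))
    slope, intercept, r_val, _, _ = sps.linregress(a, m)

    precision = ci = None
    if labelled_sample is not None:
        correct, n = labelled_sample
        if not 0 <= correct <= n or n <= 0:
            raise ValueError("labelled_sample must be (n_correct, n_labelled)")
        precision = correct / n
        lo, hi = proportion_confint(correct, n, method="wilson")
        ci = (float(lo), float(hi))
    return ValidationReport(
        n_genera=len(shared),
        spearman_rho=float(rho),
        pearson_r=float(r),
        mae=mae,
        rmse=rmse,
        ols_slope=float(slope),
        ols_intercept=float(intercept),
        r_squared=float(r_val**2),
        precision=precision,
        precision_ci=ci,
    )
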