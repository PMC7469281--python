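"""Secretome filtering and gene-set over-representation analysis.

The workflow mirrors the standard antibody-array analysis: keep analytes
whose normalized intensity exceeds a cutoff (strictly greater than 0.2 on
the 0-1 array scale), then test the retained list against a GMT library of
gene sets with the one-sided Fisher / hypergeometric test, correcting for
the number of terms with Bonferroni.  A term is called significant at
Bonferroni-adjusted p < 0.05.

GMT files carry no gene universe, so the universe size is an explicit
library-level parameter (default 20,000, roughly the protein-coding genome).
Gene matching is case-insensitive exact string match after whitespace
trimming; no alias resolution is attempted.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from math import isfinite
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "DEFAULT_UNIVERSE",
    "SIGNIFICANCE_LEVEL",
    "INTENSITY_THRESHOLD",
    "SecretomeTable",
    "GeneSetLibrary",
    "EnrichmentResult",
    "filter_secretome",
    "hypergeometric_pvalue",
    "enrich",
    "read_secretome",
    "write_analyte_list",
    "read_gmt",
    "write_gmt",
    "results_to_dataframe",
    "write_results_tsv",
]

logger = logging.getLogger(__name__)

DEFAULT_UNIVERSE = 20_000
SIGNIFICANCE_LEVEL = 0.05
INTENSITY_THRESHOLD = 0.2


@dataclass
class SecretomeTable:
    """Analyte name -> normalized intensity (nonnegative, finite)."""

    entries: dict[str, float]

    def __post_init__(self):
        for name, value in self.entries.items():
            if not isfinite(value) or value < 0:
                raise ValueError(
                    f"intensity for {name!r} must be finite and >= 0, got {value!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class GeneSetLibrary:
    """Named gene sets plus the universe size for the hypergeometric null."""

    terms: dict[str, frozenset[str]]
    universe: int = DEFAULT_UNIVERSE

    def __post_init__(self):
        self.terms = {t: frozenset(g.strip().upper() for g in genes) for t, genes in self.terms.items()}
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} is empty")
            if len(genes) > self.universe:
                raise ValueError(
                    f"term {term!r} has {len(genes)} genes, exceeding universe {self.universe}"
                )

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class EnrichmentResult:
    term: str
    overlap: int
    query_size: int
    term_size: int
    universe: int
    raw_p: float
    adjusted_p: float
    rank: int

    @property
    def significant(self) -> bool:
        return self.adjusted_p < SIGNIFICANCE_LEVEL


def filter_secretome(table: SecretomeTable, threshold: float = INTENSITY_THRESHOLD) -> list[str]:
    """Analytes with intensity strictly greater than *threshold*, sorted by
    descending intensity (ties broken by name)."""
    if not isfinite(threshold):
        raise ValueError("threshold must be finite")
    kept = [(name, value) for name, value in table.entries.items() if value > threshold]
    kept.sort(key=lambda item: (-item[1], item[0]))
    return [name for name, _ in kept]


def hypergeometric_pvalue(overlap: int, query_size: int, term_size: int, universe: int) -> float:
    """Upper-tail P(X >= overlap) for X ~ Hypergeom(universe, term_size,
    query_size); equals the one-sided Fisher exact p of the 2x2 table."""
    if not (0 <= overlap <= min(query_size, term_size)):
        raise ValueError(
            f"overlap {overlap} outside [0, min(query={query_size}, term={term_size})]"
        )
    if query_size > universe or term_size > universe:
        raise ValueError("query and term sizes must not exceed the universe")
    if overlap == 0:
        return 1.0
    return float(hypergeom.sf(overlap - 1, universe, term_size, query_size))


def _normalize_query(query: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for name in query:
        key = name.strip().upper()
        if key:
            seen.setdefault(key)
    return list(seen)


def enrich(query: Iterable[str], library: GeneSetLibrary) -> list[EnrichmentResult]:
    """One-sided over-representation test of *query* against every library
    term, Bonferroni-corrected over the term count and ranked by
    (adjusted p, raw p, term name)."""
    genes = _normalize_query(query)
    if not genes:
        raise ValueError("query is empty after normalization")
    if not library.terms:
        raise ValueError("library has no terms")
    query_set = set(genes)
    if len(query_set) > library.universe:
        raise ValueError("query larger than the library universe")
    m = len(library.terms)
    logger.info(
        "enrichment: %d query genes vs %d terms, universe=%d, Bonferroni m=%d",
        len(query_set), m, library.universe, m,
    )
    results = []
    for term, members in library.terms.items():
        overlap = len(query_set & members)
        raw_p = hypergeometric_pvalue(overlap, len(query_set), len(members), library.universe)
        adjusted = min(1.0, m * raw_p)
        results.append(
            EnrichmentResult(
                term=term,
                overlap=overlap,
                query_size=len(query_set),
                term_size=len(members),
                universe=library.universe,
                raw_p=raw_p,
                adjusted_p=adjusted,
                rank=0,
            )
        )
    results.sort(key=lambda r: (r.adjusted_p, r.raw_p, r.term))
    for i, result in enumerate(results, start=1):
        result.rank = i
    return results


# --------------------------------------------------------------------------
# File formats


def read_secretome(path: str | Path) -> SecretomeTable:
    """Read a two-column analyte/intensity table (TSV or CSV, header
    optional)."""
    text = Path(path).read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (analyte, intensity)")
    # Drop a header row if the second column is not numeric there.
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    names = df.iloc[:, 0].astype(str).str.strip()
    values = pd.to_numeric(df.iloc[:, 1], errors="raise").astype(float)
    if names.duplicated().any():
        dupes = sorted(names[names.duplicated()].unique())
        raise ValueError(f"{path}: duplicate analyte(s): {', '.join(dupes)}")
    return SecretomeTable(dict(zip(names, values)))


def write_analyte_list(names: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(names) + ("\n" if names else ""))


def read_gmt(path: str | Path, universe: int = DEFAULT_UNIVERSE) -> GeneSetLibrary:
    """Read a GMT library (term <tab> description <tab> genes...)."""
    terms: dict[str, frozenset[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs term, description, >=1 gene")
        term = fields[0].strip()
        if term in terms:
            raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
        genes = frozenset(g.strip() for g in fields[2:] if g.strip())
        if not genes:
            raise ValueError(f"{path}:{lineno}: term {term!r} has no genes")
        terms[term] = genes
    if not terms:
        raise ValueError(f"{path}: empty GMT file")
    return GeneSetLibrary(terms, universe=universe)


def write_gmt(library: GeneSetLibrary, path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([term, description, *sorted(genes)])
        for term, genes in library.terms.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def results_to_dataframe(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "term": [r.term for r in results],
            "overlap": [r.overlap for r in results],
            "term_size": [r.term_size for r in results],
            "query_size": [r.query_size for r in results],
            "raw_p": [r.raw_p for r in results],
            "bonferroni_p": [r.adjusted_p for r in results],
            "significant": [r.significant for r in results],
        }
    )


def write_results_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    results_to_dataframe(results).to_csv(path, sep="\t", index=False)
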