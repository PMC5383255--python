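"""Readers and writers for the external formats.

* interaction edge lists in the STRING ``protein.links`` dialect
  (whitespace-separated ``protein1 protein2 combined_score``, optionally
  gzip-compressed, optional header line),
* seed-gene lists (one ID per line, ``#`` comments),
* GMT term-annotation sets (``term<TAB>description<TAB>gene...``),
* TSV result tables.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import IO, Iterable, Mapping

from .errors import ParseError, ValidationError
from .network import InteractionRecord, SeedSet, WeightedNetwork, make_seed_set

logger = logging.getLogger(__name__)


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_string_links(path: str | Path, min_score: int = 150) -> list[InteractionRecord]:
    """Parse a STRING-style edge list into deduplicated interaction records.

    Lines are ``ID_A ID_B SCORE`` (any whitespace). A first line whose third
    column is not an integer is treated as a header and skipped. Reciprocal
    or repeated unordered pairs collapse to a single record keeping the
    maximum score. Records scoring below ``min_score`` are dropped.

    Raises
    ------
    ParseError
        on a wrong column count or non-integer score (header excepted),
        naming the line number.
    ValidationError
        on a score outside [0, 1000].
    """
    best: dict[tuple[str, str], InteractionRecord] = {}
    n_dropped = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns, got {len(fields)}")
            a, b, raw_score = fields
            try:
                score = int(raw_score)
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise ParseError(
                    f"{path}: line {lineno}: non-integer score {raw_score!r}"
                ) from None
            if not 0 <= score <= 1000:
                raise ValidationError(
                    f"{path}: line {lineno}: score {score} outside [0, 1000]"
                )
            if score < min_score:
                n_dropped += 1
                continue
            rec = InteractionRecord(a, b, score)
            key = rec.canonical()
            prev = best.get(key)
            if prev is None or rec.score > prev.score:
                best[key] = InteractionRecord(key[0], key[1], rec.score)
    if n_dropped:
        logger.info("dropped %d interaction(s) below min_score=%d", n_dropped, min_score)
    return [best[k] for k in sorted(best)]


def write_string_links(records: Iterable[InteractionRecord], path: str | Path,
                       header: bool = True) -> None:
    """Write records in the same dialect ``read_string_links`` consumes."""
    with _open_text(path, "wt") as fh:
        if header:
            fh.write("protein1 protein2 combined_score\n")
        for rec in sorted(records):
            fh.write(f"{rec.node_a} {rec.node_b} {rec.score}\n")


def read_seed_set(path: str | Path, network: WeightedNetwork,
                  label: str | None = None) -> SeedSet:
    """Read a one-ID-per-line seed list and bind it to the network.

    IDs absent from the network are discarded (logged); duplicates collapse;
    an empty surviving set is fatal.
    """
    ids: list[str] = []
    with _open_text(path) as fh:
        for line in fh:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            ids.append(token.split()[0])
    if not ids:
        raise ValidationError(f"{path}: seed file contains no IDs")
    return make_seed_set(ids, network, label=label or Path(path).stem)


def write_seed_list(ids: Iterable[str], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")


def read_gmt(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read GMT term sets: term ID -> tuple of member gene IDs (order kept)."""
    terms: dict[str, tuple[str, ...]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT needs term, description and >=1 gene"
                )
            term = fields[0]
            if term in terms:
                raise ParseError(f"{path}: line {lineno}: duplicate term {term!r}")
            genes = tuple(g for g in fields[2:] if g)
            if not genes:
                raise ParseError(f"{path}: line {lineno}: term {term!r} has no genes")
            terms[term] = genes
    if not terms:
        raise ValidationError(f"{path}: GMT file contains no terms")
    return terms


def write_gmt(terms: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for term, genes in terms.items():
            genes = list(genes)
            fh.write("\t".join([term, term] + genes) + "\n")


def write_tsv(rows: Iterable[Mapping[str, object]], path: str | Path,
              columns: list[str]) -> None:
    """Write a deterministic TSV with header; floats are rendered with repr."""
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(c)) for c in columns) + "\n")


def _fmt(value: object) -> str:
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)
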