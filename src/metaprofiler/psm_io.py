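"""Peptide-spectrum-match tables: reading, target-decoy FDR filtering, merging.

Each search engine produces one tab-separated PSM table per sample.  Records
are validated per (sample, engine) stratum with a target-decoy filter at a
1% false-discovery-rate default, then engines are merged into one
identification set per sample.  The FDR estimator is #decoys / #targets in
the score-sorted prefix; ties in score are kept or dropped together because
the threshold applies to the score value, not the rank.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import IO, Iterable

DEFAULT_FDR = 0.01

_COLUMNS = (
    "spectrum_key",
    "sample_id",
    "engine",
    "peptide",
    "score",
    "accessions",
    "is_decoy",
)


class PsmFormatError(Exception):
    """Malformed PSM table row or header."""


class PsmConsistencyError(Exception):
    """Contradictory records, e.g. one spectrum claimed by two samples."""


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match.

    ``engines`` is a sorted tuple: a single label as read from one engine's
    table, possibly several after :func:`merge_engines` collapses identical
    identifications made by different engines.
    """

    spectrum_key: str
    sample_id: str
    engines: tuple[str, ...]
    peptide: str
    score: float
    accessions: tuple[str, ...]
    is_decoy: bool

    def __post_init__(self):
        if not self.peptide:
            raise ValueError("peptide must be non-empty")
        if not self.accessions:
            raise ValueError("accessions must be non-empty")


@dataclass
class SearchResultSet:
    records: list[PsmRecord] = field(default_factory=list)

    @property
    def samples(self) -> set[str]:
        return {r.sample_id for r in self.records}

    @property
    def engines(self) -> set[str]:
        return {e for r in self.records for e in r.engines}

    def __len__(self) -> int:
        return len(self.records)

    def distinct_spectra(self) -> set[str]:
        return {r.spectrum_key for r in self.records}


def read_psm_table(source: IO[str]) -> SearchResultSet:
    """Parse the tab-separated PSM dialect, rejecting malformed rows by line.

    Header columns: spectrum_key, sample_id, engine, peptide, score,
    accessions (semicolon-joined), is_decoy (0/1).
    """
    header_line = source.readline().rstrip("\n")
    header = header_line.split("\t")
    missing = [c for c in _COLUMNS if c not in header]
    if missing:
        raise PsmFormatError(f"missing column(s) {missing} in header {header}")
    idx = {c: header.index(c) for c in _COLUMNS}

    records: list[PsmRecord] = []
    seen: set[tuple] = set()
    for lineno, line in enumerate(source, start=2):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < len(header):
            raise PsmFormatError(f"line {lineno}: expected {len(header)} fields")
        try:
            score = float(fields[idx["score"]])
        except ValueError:
            raise PsmFormatError(
                f"line {lineno}: non-numeric score {fields[idx['score']]!r}"
            ) from None
        accessions = tuple(a for a in fields[idx["accessions"]].split(";") if a)
        if not accessions:
            raise PsmFormatError(f"line {lineno}: empty accessions")
        decoy_field = fields[idx["is_decoy"]]
        if decoy_field not in ("0", "1"):
            raise PsmFormatError(f"line {lineno}: is_decoy must be 0/1")
        if not fields[idx["peptide"]]:
            raise PsmFormatError(f"line {lineno}: empty peptide")
        record = PsmRecord(
            spectrum_key=fields[idx["spectrum_key"]],
            sample_id=fields[idx["sample_id"]],
            engines=(fields[idx["engine"]],),
            peptide=fields[idx["peptide"]],
            score=score,
            accessions=accessions,
            is_decoy=decoy_field == "1",
        )
        key = (record.spectrum_key, record.engines, record.peptide, record.accessions)
        if key in seen:
            continue
        seen.add(key)
        records.append(record)
    return SearchResultSet(records=records)


def write_psm_table(results: SearchResultSet, sink: IO[str]) -> None:
    """Inverse of :func:`read_psm_table`; merged records emit one row per engine."""
    sink.write("\t".join(_COLUMNS) + "\n")
    for r in sorted(
        results.records, key=lambda r: (r.sample_id, r.spectrum_key, r.peptide)
    ):
        for engine in r.engines:
            sink.write(
                "\t".join(
                    (
                        r.spectrum_key,
                        r.sample_id,
                        engine,
                        r.peptide,
                        repr(r.score),
                        ";".join(r.accessions),
                        "1" if r.is_decoy else "0",
                    )
                )
                + "\n"
            )


def fdr_threshold(
    scores: Iterable[float], decoys: Iterable[bool], fdr_target: float
) -> float | None:
    """Score threshold t* for one stratum, or None if no prefix qualifies.

    Records are ranked by descending score with equal scores grouped; t* is
    the lowest score such that #decoys(score >= t*) / #targets(score >= t*)
    <= fdr_target.  A prefix with zero targets never qualifies.
    """
    pairs = sorted(zip(scores, decoys), key=lambda p: -p[0])
    best: float | None = None
    n_targets = n_decoys = 0
    i = 0
    while i < len(pairs):
        j = i
        while j < len(pairs) and pairs[j][0] == pairs[i][0]:
            n_decoys += pairs[j][1]
            n_targets += not pairs[j][1]
            j += 1
        if n_targets > 0 and n_decoys / n_targets <= fdr_target:
            best = pairs[i][0]
        i = j
    return best


def filter_by_fdr(
    results: SearchResultSet, fdr_target: float = DEFAULT_FDR
) -> SearchResultSet:
    """Target-decoy filter per (sample, engine) stratum.

    Returns only target records at or above each stratum's threshold; decoys
    are removed from the output.  Single-peptide identifications are kept
    (one-peptide rule).  A stratum with no qualifying prefix, or no targets
    at all, yields empty output with a warning.
    """
    if not 0 < fdr_target <= 1:
        raise ValueError("fdr_target must be in (0, 1]")
    strata: dict[tuple[str, str], list[PsmRecord]] = {}
    for r in results.records:
        for engine in r.engines:
            strata.setdefault((r.sample_id, engine), []).append(r)

    kept: list[PsmRecord] = []
    for (sample_id, engine), recs in sorted(strata.items()):
        if not any(not r.is_decoy for r in recs):
            warnings.warn(f"stratum ({sample_id}, {engine}) has no target records")
            continue
        t_star = fdr_threshold(
            [r.score for r in recs], [r.is_decoy for r in recs], fdr_target
        )
        if t_star is None:
            warnings.warn(
                f"stratum ({sample_id}, {engine}): no score threshold attains "
                f"FDR <= {fdr_target}; stratum dropped"
            )
            continue
        kept.extend(
            replace(r, engines=(engine,))
            for r in recs
            if not r.is_decoy and r.score >= t_star
        )
    return SearchResultSet(records=kept)


def merge_engines(sets: Iterable[SearchResultSet]) -> SearchResultSet:
    """Union already-filtered engine results into one set per pipeline run.

    Identical (spectrum_key, peptide, accessions) identifications from
    different engines collapse to one record tagged with all contributing
    engines (best score kept); the same spectrum with different peptides
    keeps every assignment — downstream spectral counting deduplicates at
    the spectrum level.
    """
    sample_of: dict[str, str] = {}
    merged: dict[tuple, PsmRecord] = {}
    for result_set in sets:
        for r in result_set.records:
            prev_sample = sample_of.setdefault(r.spectrum_key, r.sample_id)
            if prev_sample != r.sample_id:
                raise PsmConsistencyError(
                    f"spectrum {r.spectrum_key} claimed by samples "
                    f"{prev_sample!r} and {r.sample_id!r}"
                )
            key = (r.spectrum_key, r.peptide, r.accessions)
            if key in merged:
                prev = merged[key]
                merged[key] = replace(
                    prev,
                    engines=tuple(sorted(set(prev.engines) | set(r.engines))),
                    score=max(prev.score, r.score),
                )
            else:
                merged[key] = r
    return SearchResultSet(records=[merged[k] for k in sorted(merged)])
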