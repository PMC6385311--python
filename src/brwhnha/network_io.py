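"""Readers and writers for association edge lists, labelled dense matrices,
score/ranking files and key=value run configs.

All index/label bookkeeping lives here.  Delimiters are auto-detected among
tab, comma and semicolon on the first line; tab is always used on write.
Identifier matching is exact and case-sensitive — no normalisation of e.g.
"hsa-mir" vs "hsa-miR", since silent case-folding creates spurious merges;
:func:`find_near_miss_ids` reports case-insensitive near misses instead.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AssociationMatrix, RunConfig, ScoreMatrix, SimilarityMatrix
from .exceptions import ParseError, ValidationError

__all__ = [
    "read_association_edgelist",
    "write_association_edgelist",
    "read_similarity_matrix",
    "write_similarity_matrix",
    "read_score_matrix",
    "write_score_matrix",
    "ranking_path_for",
    "read_run_config",
    "find_near_miss_ids",
]

_DELIMITERS = ("\t", ",", ";")
_HEADER_TOKENS = {"mirna", "mirna_id", "mir", "disease", "disease_id", "id"}
_ASYMMETRY_WARN = 1e-8


def _detect_delimiter(first_line: str) -> str:
    for d in _DELIMITERS:
        if d in first_line:
            return d
    return "\t"


def find_near_miss_ids(ids_a, ids_b) -> list[tuple[str, str]]:
    """Pairs (a, b) that match case-insensitively but not exactly.

    Used in validation reports so that deliberate case distinctions
    ("hsa-mir" vs "hsa-miR") surface instead of silently failing to merge.
    """
    by_fold: dict[str, list[str]] = {}
    for b in ids_b:
        by_fold.setdefault(b.lower(), []).append(b)
    out = []
    set_b = set(ids_b)
    for a in ids_a:
        if a in set_b:
            continue
        for b in by_fold.get(a.lower(), []):
            out.append((a, b))
    return out


def read_association_edgelist(
    path,
    mirna_universe: list[str] | None = None,
    disease_universe: list[str] | None = None,
) -> AssociationMatrix:
    """Read a two-column (miRNA id, disease id) edge list into a 0/1 matrix.

    An optional header line whose fields look like column names is skipped.
    With explicit universes the axes follow them exactly (user order is never
    re-sorted) and any id outside a universe is an error; without universes
    the axes are the sorted unique ids occurring in the file.  Duplicate
    pairs collapse to a single 1.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    pairs: list[tuple[str, str]] = []
    delim = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if delim is None:
            delim = _detect_delimiter(line)
        fields = [f.strip() for f in line.split(delim)]
        if len(fields) != 2:
            raise ParseError(
                f"{path}:{lineno}: expected 2 fields, got {len(fields)}: {line!r}"
            )
        if lineno == 1 and (fields[0].lower() in _HEADER_TOKENS
                            or fields[1].lower() in _HEADER_TOKENS):
            continue
        pairs.append((fields[0], fields[1]))

    if mirna_universe is not None:
        mirna_ids = list(mirna_universe)
    else:
        mirna_ids = sorted({m for m, _ in pairs})
    if disease_universe is not None:
        disease_ids = list(disease_universe)
    else:
        disease_ids = sorted({d for _, d in pairs})

    m_index = {m: i for i, m in enumerate(mirna_ids)}
    d_index = {d: j for j, d in enumerate(disease_ids)}
    values = np.zeros((len(mirna_ids), len(disease_ids)), dtype=np.int8)
    for m, d in pairs:
        if m not in m_index:
            near = find_near_miss_ids([m], mirna_ids)
            hint = f" (case near-miss: {near})" if near else ""
            raise ValidationError(f"miRNA id {m!r} not in the provided universe{hint}")
        if d not in d_index:
            near = find_near_miss_ids([d], disease_ids)
            hint = f" (case near-miss: {near})" if near else ""
            raise ValidationError(f"disease id {d!r} not in the provided universe{hint}")
        values[m_index[m], d_index[d]] = 1
    return AssociationMatrix(values, mirna_ids, disease_ids)


def write_association_edgelist(assoc: AssociationMatrix, path) -> None:
    """Write the 1-entries as a tab-separated (miRNA, disease) edge list."""
    path = Path(path)
    rows, cols = np.nonzero(assoc.values)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("mirna\tdisease\n")
        for i, j in zip(rows, cols):
            fh.write(f"{assoc.mirna_ids[i]}\t{assoc.disease_ids[j]}\n")


def read_similarity_matrix(path, kind: str = "semantic") -> SimilarityMatrix:
    """Read a labelled dense square matrix (header row + first-column labels).

    The matrix is symmetrised as (S + S^T)/2; when the maximum asymmetry
    exceeds 1e-8 a warning is emitted.  Labels are preserved in file order.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    delim = _detect_delimiter(first)
    df = pd.read_csv(path, sep=delim, index_col=0, dtype=str)
    ids = [str(c) for c in df.columns]
    row_ids = [str(r) for r in df.index]
    if len(ids) != len(row_ids):
        raise ValidationError(
            f"{path}: matrix is not square ({len(row_ids)} rows x {len(ids)} columns)"
        )
    if row_ids != ids:
        raise ValidationError(f"{path}: row labels do not match column labels")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, row in enumerate(df.itertuples(index=False)):
            for j, cell in enumerate(row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"{path}: non-numeric cell at row {row_ids[i]!r}, "
                        f"column {ids[j]!r}: {cell!r}"
                    ) from None
        raise
    asym = float(np.abs(values - values.T).max()) if values.size else 0.0
    if asym > _ASYMMETRY_WARN:
        warnings.warn(
            f"{path}: symmetrizing matrix with max asymmetry {asym:.3e}",
            stacklevel=2,
        )
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values, ids, kind=kind)


def write_similarity_matrix(sim: SimilarityMatrix, path) -> None:
    df = pd.DataFrame(sim.values, index=sim.ids, columns=sim.ids)
    df.to_csv(path, sep="\t")


def read_score_matrix(path, stage: str = "walk_output") -> ScoreMatrix:
    """Read back a labelled dense score matrix written by write_score_matrix."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline()
    delim = _detect_delimiter(first)
    df = pd.read_csv(path, sep=delim, index_col=0)
    return ScoreMatrix(
        df.to_numpy(dtype=float),
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        stage=stage,
    )


def ranking_path_for(path) -> Path:
    """Companion long-form ranking file path for a score-matrix path."""
    path = Path(path)
    return path.with_name(path.stem + ".ranking" + (path.suffix or ".tsv"))


def write_score_matrix(
    scores: ScoreMatrix, path, assoc: AssociationMatrix | None = None
) -> None:
    """Write the dense labelled score matrix plus a companion ranking file.

    The ranking file holds (disease, miRNA, score, rank, is_known) sorted by
    disease (matrix column order) then descending score, ties broken by
    lexicographic miRNA id.  ``is_known`` is taken from ``assoc`` when given,
    else 0.  Floats are written with shortest-roundtrip repr so read-back is
    exact.
    """
    path = Path(path)
    pd.DataFrame(scores.values, index=scores.mirna_ids, columns=scores.disease_ids).to_csv(
        path, sep="\t"
    )
    if assoc is not None and (
        assoc.mirna_ids != scores.mirna_ids or assoc.disease_ids != scores.disease_ids
    ):
        raise ValidationError("association matrix labels do not match the score matrix")
    with ranking_path_for(path).open("w", encoding="utf-8") as fh:
        fh.write("disease\tmirna\tscore\trank\tis_known\n")
        for j, did in enumerate(scores.disease_ids):
            order = sorted(
                range(len(scores.mirna_ids)),
                key=lambda i: (-scores.values[i, j], scores.mirna_ids[i]),
            )
            for rank, i in enumerate(order, start=1):
                known = int(assoc.values[i, j]) if assoc is not None else 0
                fh.write(
                    f"{did}\t{scores.mirna_ids[i]}\t{scores.values[i, j]!r}"
                    f"\t{rank}\t{known}\n"
                )


def read_run_config(path) -> dict[str, str]:
    """Parse a key=value config file (one pair per line, '#' comments)."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ParseError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
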