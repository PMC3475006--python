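"""Readers and writers for the TSV/BED data bundle.

Everything on disk is tab-delimited text. Annotation tables carry the columns
``id, chromosome, start, end`` (header required, 1-based inclusive
coordinates); BED files (0-based half-open, no header) are accepted for
annotation and converted at this boundary. Data matrices are features x
samples with the feature ID in the first column and sample IDs in the header;
``NA`` or an empty field marks a missing value.

A "matched bundle" directory, as written by :func:`write_matched`, holds the
row-aligned matched dataset: ``features.tsv`` (per-row gene annotation, in
order), the three summarized CN matrices, the expression matrix,
``provenance.tsv`` and ``run_metadata.yaml``. Matched bundles are read back
positionally because genes may recur under the split/expand extensions;
platform input bundles require unique feature IDs and are aligned to the
annotation by ID regardless of row order.
"""

from __future__ import annotations

import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .model import (
    CopyNumberSet,
    ExpressionSet,
    FeatureAnnotation,
    MatchedPair,
)

__all__ = [
    "read_annotation",
    "write_annotation",
    "read_matrix",
    "write_matrix",
    "read_copynumber_bundle",
    "read_expression_bundle",
    "write_simulated_bundle",
    "write_matched",
    "read_matched",
    "load_example_locus",
]

_ANNOTATION_COLUMNS = ("id", "chromosome", "start", "end")


class FormatError(ValueError):
    """Malformed input file; the message names file, line and field."""


def read_annotation(path, fmt: str = "tsv") -> list[FeatureAnnotation]:
    """Read a feature annotation table (TSV with header, or headerless BED).

    TSV columns: ``id, chromosome, start, end`` (1-based inclusive). BED rows
    (``chrom  start  end  [name]``, 0-based half-open) are converted to the
    internal 1-based inclusive convention; unnamed BED rows get positional
    IDs. Rows with non-integer or inverted coordinates are rejected with an
    error naming the file, line and offending field.
    """
    path = Path(path)
    if fmt == "tsv":
        return _read_annotation_tsv(path)
    if fmt == "bed":
        return _read_annotation_bed(path)
    raise ValueError(f"unknown annotation format {fmt!r} (use 'tsv' or 'bed')")


def _parse_int(value, path: Path, line: int, field: str) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise FormatError(
            f"{path}, line {line}: field {field!r} must be an integer, got {value!r}"
        ) from None


def _read_annotation_tsv(path: Path) -> list[FeatureAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    rename = {"feature_id": "id", "chrom": "chromosome", "chr": "chromosome"}
    df = df.rename(columns=rename)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation column(s) {missing}")
    out = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        d = dict(zip(df.columns, row))
        start = _parse_int(d["start"], path, row_no, "start")
        end = _parse_int(d["end"], path, row_no, "end")
        try:
            out.append(FeatureAnnotation(str(d["id"]), str(d["chromosome"]), start, end))
        except ValueError as exc:
            raise FormatError(f"{path}, line {row_no}: {exc}") from None
    return out


def _read_annotation_bed(path: Path) -> list[FeatureAnnotation]:
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise FormatError(
                    f"{path}, line {line_no}: BED rows need at least 3 fields, got {len(parts)}"
                )
            start0 = _parse_int(parts[1], path, line_no, "start")
            end0 = _parse_int(parts[2], path, line_no, "end")
            name = parts[3] if len(parts) > 3 else f"feature_{line_no}"
            try:
                out.append(FeatureAnnotation(name, parts[0], start0 + 1, end0))
            except ValueError as exc:
                raise FormatError(f"{path}, line {line_no}: {exc}") from None
    return out


def write_annotation(features: Sequence[FeatureAnnotation], path) -> None:
    df = pd.DataFrame(
        {
            "id": [f.feature_id for f in features],
            "chromosome": [f.chromosome for f in features],
            "start": [f.start for f in features],
            "end": [f.end for f in features],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read a feature x sample matrix: first column IDs, header row samples.

    ``NA`` and empty fields become missing values; the frame is indexed by
    feature ID in file order.
    """
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=["NA", ""], keep_default_na=False
    )
    df.index = df.index.astype(str)
    return df.astype(float)


def write_matrix(values: np.ndarray, feature_ids, samples, path, index_name="feature_id") -> None:
    df = pd.DataFrame(np.asarray(values), index=list(feature_ids), columns=list(samples))
    df.index.name = index_name
    df.to_csv(path, sep="\t", na_rep="NA")


def _align(df: pd.DataFrame, features: list[FeatureAnnotation], path) -> pd.DataFrame:
    ids = [f.feature_id for f in features]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: annotation feature IDs are not unique")
    missing = sorted(set(ids) - set(df.index))
    extra = sorted(set(df.index) - set(ids))
    if missing or extra:
        raise FormatError(
            f"{path}: matrix/annotation ID mismatch; "
            f"missing from matrix: {missing[:10]}{'...' if len(missing) > 10 else ''}; "
            f"absent from annotation: {extra[:10]}{'...' if len(extra) > 10 else ''}"
        )
    return df.loc[ids]


def read_copynumber_bundle(
    annotation_path, normalized_path, segmented_path, calls_path, fmt: str = "tsv"
) -> CopyNumberSet:
    """Assemble a CopyNumberSet from an annotation table and three matrices.

    Matrices are aligned to the annotation by feature ID (row order in the
    files is irrelevant) and must cover exactly the annotated features; the
    result is canonicalized (sorted by chromosome, start, end).
    """
    features = read_annotation(annotation_path, fmt)
    norm = _align(read_matrix(normalized_path), features, normalized_path)
    seg = _align(read_matrix(segmented_path), features, segmented_path)
    calls = _align(read_matrix(calls_path), features, calls_path)
    if not (list(norm.columns) == list(seg.columns) == list(calls.columns)):
        raise FormatError("copy number matrices disagree on sample columns")
    return CopyNumberSet(
        features, list(norm.columns), norm.to_numpy(), seg.to_numpy(), calls.to_numpy()
    ).canonicalize()


def read_expression_bundle(annotation_path, expression_path, fmt: str = "tsv") -> ExpressionSet:
    features = read_annotation(annotation_path, fmt)
    expr = _align(read_matrix(expression_path), features, expression_path)
    return ExpressionSet(features, list(expr.columns), expr.to_numpy()).canonicalize()


def write_simulated_bundle(cn: CopyNumberSet, ge: ExpressionSet, truth, out_dir) -> None:
    """Write a simulated dataset as the standard platform-input TSV bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotation(cn.features, out / "cn_annotation.tsv")
    write_matrix(cn.normalized, cn.feature_ids, cn.samples, out / "cn_normalized.tsv")
    write_matrix(cn.segmented, cn.feature_ids, cn.samples, out / "cn_segmented.tsv")
    write_matrix(cn.calls, cn.feature_ids, cn.samples, out / "cn_calls.tsv")
    write_annotation(ge.features, out / "ge_annotation.tsv")
    write_matrix(ge.expression, ge.feature_ids, ge.samples, out / "expression.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def write_matched(
    pair: MatchedPair,
    out_dir,
    metadata: Mapping[str, object] | None = None,
    unmatched_gene_ids: Iterable[str] = (),
) -> None:
    """Write a matched bundle: row-aligned matrices, provenance, run metadata.

    Rows of all files are aligned with the match entries. The metadata file
    records the method and parameters plus an unmatched-gene report; its
    timestamp is the only non-deterministic byte in the bundle.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cn, ge = pair.cn_summary, pair.expression
    write_annotation(cn.features, out / "features.tsv")
    write_matrix(cn.normalized, cn.feature_ids, cn.samples, out / "cn_normalized.tsv")
    write_matrix(cn.segmented, cn.feature_ids, cn.samples, out / "cn_segmented.tsv")
    write_matrix(cn.calls, cn.feature_ids, cn.samples, out / "cn_calls.tsv")
    write_matrix(ge.expression, ge.feature_ids, ge.samples, out / "expression.tsv")
    pair.provenance.to_csv(out / "provenance.tsv", sep="\t", index=False)
    meta = dict(metadata or {})
    meta.setdefault("n_rows", pair.n_rows)
    meta["unmatched_gene_ids"] = sorted(unmatched_gene_ids)
    meta["written_at"] = datetime.datetime.now().isoformat(timespec="seconds")
    with open(out / "run_metadata.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_matched(bundle_dir) -> MatchedPair:
    """Read a matched bundle back, positionally (duplicate gene IDs allowed)."""
    out = Path(bundle_dir)
    features = read_annotation(out / "features.tsv")
    ids = [f.feature_id for f in features]

    def load(name):
        df = read_matrix(out / name)
        if list(df.index) != ids:
            raise FormatError(
                f"{out / name}: row IDs do not match features.tsv row-for-row"
            )
        return df

    norm = load("cn_normalized.tsv")
    seg = load("cn_segmented.tsv")
    calls = load("cn_calls.tsv")
    expr = load("expression.tsv")
    provenance = pd.read_csv(out / "provenance.tsv", sep="\t", dtype=str)
    provenance["n_cn_features"] = provenance["n_cn_features"].astype(int)
    cn = CopyNumberSet(
        features, list(norm.columns), norm.to_numpy(), seg.to_numpy(), calls.to_numpy()
    )
    ge = ExpressionSet(features, list(expr.columns), expr.to_numpy())
    return MatchedPair(cn, ge, provenance)


def load_example_locus() -> tuple[FeatureAnnotation, list[FeatureAnnotation]]:
    """The packaged worked-example locus on chromosome 14.

    A real Agilent expression probe (A_23_P140170, chr14:38570874-38642188,
    from a glioblastoma copy-number/expression study) together with the 25
    surrounding probes of an Agilent 244K aCGH layout. Useful as a small,
    fully worked instance on which every matching procedure gives a known
    answer.
    """
    data_dir = Path(__file__).parent / "data"
    genes = read_annotation(data_dir / "example_ge_annotation.tsv")
    probes = read_annotation(data_dir / "example_cn_annotation.tsv")
    return genes[0], probes
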