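"""TSV readers and writers for all pipeline tables.

One on-disk dialect everywhere: tab-separated, UTF-8, '.' decimal, one
header row.  Schemas::

    counts      gene_id  donor_id  fraction_class  count
    donors      donor_id  sex  condition
    trace       position  absorbance
    abundance   feature_id  donor_id  dataset  value
    genesets    set_id  feature_id
    differential  feature  log2_fc  p_value  significant  two_fold  direction

Infinite and undefined values are serialized as ``inf`` / ``-inf`` / ``nan``
and parsed back to the same sentinels, so writer->reader is the identity on
valid tables.
"""
from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (
    AbundanceTable,
    DifferentialResult,
    DonorMeta,
    EnrichmentResult,
    FormatError,
    FractionClass,
    FractionCountMatrix,
    GradientTrace,
    N_CLASSES,
    TranslationStat,
    ValidationError,
)

log = logging.getLogger("polyte")

_FLOAT_FMT = "%.17g"  # round-trippable through float()


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed TSV
        raise FormatError(f"{path}: cannot parse TSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def _parse_float(raw: str, path: Path, col: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise FormatError(f"{path}: cannot parse {col} value {raw!r}") from None


def read_donors(path: str | Path) -> list[DonorMeta]:
    """Read donor metadata (donor_id, sex, optional condition)."""
    df = _read_tsv(path, ["donor_id", "sex"])
    donors = []
    for _, row in df.iterrows():
        condition = row.get("condition", "") or "unstimulated"
        donors.append(DonorMeta(row["donor_id"], row["sex"], condition))
    ids = [d.donor_id for d in donors]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"{path}: duplicate donor ids")
    return donors


def write_donors(donors: Sequence[DonorMeta], path: str | Path) -> None:
    pd.DataFrame(
        {
            "donor_id": [d.donor_id for d in donors],
            "sex": [d.sex for d in donors],
            "condition": [d.condition for d in donors],
        }
    ).to_csv(path, sep="\t", index=False)


def read_fraction_counts(
    counts_path: str | Path, donors_path: str | Path
) -> FractionCountMatrix:
    """Read a fraction-resolved count table plus its donor metadata.

    Cells absent from the file default to 0 with a logged warning (3'-tag
    RNA-seq legitimately yields zero counts).  Unknown fraction-class labels
    are format errors; negative counts and duplicate (gene, donor, class)
    rows are validation errors.
    """
    counts_path = Path(counts_path)
    donors = read_donors(donors_path)
    donor_ids = [d.donor_id for d in donors]
    df = _read_tsv(counts_path, ["gene_id", "donor_id", "fraction_class", "count"])

    class_names = {c.name for c in FractionClass}
    bad = sorted(set(df["fraction_class"]) - class_names)
    if bad:
        raise FormatError(f"{counts_path}: unknown fraction_class labels {bad}")
    unknown_donors = sorted(set(df["donor_id"]) - set(donor_ids))
    if unknown_donors:
        raise ValidationError(
            f"{counts_path}: donors {unknown_donors} not in donor metadata"
        )

    genes = list(dict.fromkeys(df["gene_id"]))
    gi = {g: i for i, g in enumerate(genes)}
    di = {d: i for i, d in enumerate(donor_ids)}

    counts = np.zeros((len(genes), len(donor_ids), N_CLASSES), dtype=np.int64)
    filled = np.zeros_like(counts, dtype=bool)
    for row in df.itertuples(index=False):
        try:
            value = int(row.count)
        except ValueError:
            raise FormatError(
                f"{counts_path}: cannot parse count {row.count!r} for {row.gene_id}"
            ) from None
        if value < 0:
            raise ValidationError(
                f"{counts_path}: negative count {value} for "
                f"({row.gene_id}, {row.donor_id}, {row.fraction_class})"
            )
        key = (gi[row.gene_id], di[row.donor_id], FractionClass[row.fraction_class].value)
        if filled[key]:
            raise ValidationError(
                f"{counts_path}: duplicate row for "
                f"({row.gene_id}, {row.donor_id}, {row.fraction_class})"
            )
        counts[key] = value
        filled[key] = True

    n_missing = int((~filled).sum())
    if n_missing:
        log.warning(
            "%s: %d (gene, donor, class) cells absent from file; filled with 0",
            counts_path,
            n_missing,
        )
    return FractionCountMatrix(genes=genes, donors=donors, counts=counts)


def write_fraction_counts(matrix: FractionCountMatrix, path: str | Path) -> None:
    rows = []
    for i, gene in enumerate(matrix.genes):
        for j, donor in enumerate(matrix.donors):
            for cls in FractionClass:
                rows.append(
                    (gene, donor.donor_id, cls.name, int(matrix.counts[i, j, cls.value]))
                )
    pd.DataFrame(rows, columns=["gene_id", "donor_id", "fraction_class", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_trace(path: str | Path) -> GradientTrace:
    df = _read_tsv(path, ["position", "absorbance"])
    path = Path(path)
    positions = [_parse_float(v, path, "position") for v in df["position"]]
    absorbance = [_parse_float(v, path, "absorbance") for v in df["absorbance"]]
    return GradientTrace(np.array(positions), np.array(absorbance))


def write_trace(trace: GradientTrace, path: str | Path) -> None:
    pd.DataFrame({"position": trace.positions, "absorbance": trace.absorbance}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_abundance(path: str | Path, donors: Sequence[DonorMeta]) -> list[AbundanceTable]:
    """Read abundance rows and split them into one table per dataset label."""
    path = Path(path)
    df = _read_tsv(path, ["feature_id", "donor_id", "dataset", "value"])
    donor_by_id = {d.donor_id: d for d in donors}
    unknown = sorted(set(df["donor_id"]) - set(donor_by_id))
    if unknown:
        raise ValidationError(f"{path}: donors {unknown} not in donor metadata")
    tables = []
    for dataset, sub in df.groupby("dataset", sort=True):
        features = list(dict.fromkeys(sub["feature_id"]))
        ids = list(dict.fromkeys(sub["donor_id"]))
        values = np.zeros((len(features), len(ids)))
        seen = np.zeros_like(values, dtype=bool)
        fi = {f: i for i, f in enumerate(features)}
        di = {d: i for i, d in enumerate(ids)}
        for row in sub.itertuples(index=False):
            v = _parse_float(row.value, path, "value")
            key = (fi[row.feature_id], di[row.donor_id])
            if seen[key]:
                raise ValidationError(
                    f"{path}: duplicate ({row.feature_id}, {row.donor_id}) in {dataset}"
                )
            values[key] = v
            seen[key] = True
        tables.append(
            AbundanceTable(
                features=features,
                donors=[donor_by_id[d] for d in ids],
                dataset=str(dataset),
                values=values,
            )
        )
    return tables


def write_abundance(tables: Iterable[AbundanceTable], path: str | Path) -> None:
    rows = []
    for table in tables:
        for i, feat in enumerate(table.features):
            for j, donor in enumerate(table.donors):
                rows.append((feat, donor.donor_id, table.dataset, table.values[i, j]))
    pd.DataFrame(rows, columns=["feature_id", "donor_id", "dataset", "value"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


_DIFF_COLUMNS = ["feature", "log2_fc", "p_value", "significant", "two_fold", "direction"]


def write_differential(results: Sequence[DifferentialResult], path: str | Path) -> None:
    """Write differential calls; ``inf``/``-inf``/``nan`` sentinels round-trip."""
    if not results:
        raise ValidationError("refusing to write an empty differential table")
    pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "log2_fc": [_FLOAT_FMT % r.log2_fc for r in results],
            "p_value": [_FLOAT_FMT % r.p_value for r in results],
            "significant": [str(r.significant) for r in results],
            "two_fold": [str(r.two_fold) for r in results],
            "direction": [r.direction for r in results],
        }
    ).to_csv(path, sep="\t", index=False)


def read_differential(path: str | Path) -> list[DifferentialResult]:
    path = Path(path)
    df = _read_tsv(path, _DIFF_COLUMNS)
    out = []
    for row in df.itertuples(index=False):
        if row.significant not in ("True", "False") or row.two_fold not in ("True", "False"):
            raise FormatError(f"{path}: boolean columns must be True/False")
        result = DifferentialResult(
            feature=row.feature,
            log2_fc=_parse_float(row.log2_fc, path, "log2_fc"),
            p_value=_parse_float(row.p_value, path, "p_value"),
            significant=row.significant == "True",
            two_fold=row.two_fold == "True",
            direction=row.direction,
        )
        out.append(result)
    return out


def read_genesets(path: str | Path) -> dict[str, set[str]]:
    df = _read_tsv(path, ["set_id", "feature_id"])
    sets: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        sets.setdefault(row.set_id, set()).add(row.feature_id)
    return sets


def read_feature_list(path: str | Path) -> set[str]:
    """One feature id per line (plain text, no header)."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "overlap_count": [r.overlap_count for r in results],
            "foreground_size": [r.foreground_size for r in results],
            "background_size": [r.background_size for r in results],
            "set_size_in_background": [r.set_size_in_background for r in results],
            "fisher_p": [_FLOAT_FMT % r.fisher_p for r in results],
            "fdr_q": [_FLOAT_FMT % r.fdr_q for r in results],
            "enriched": [str(r.enriched) for r in results],
        }
    ).to_csv(path, sep="\t", index=False)


def write_translation_stats(
    stats: Sequence[TranslationStat],
    path: str | Path,
    differential: dict[str, DifferentialResult] | None = None,
) -> None:
    """Write per-gene TR/STR values, summaries, and (optionally) group calls."""
    if not stats:
        raise ValidationError("refusing to write an empty statistics table")
    donor_ids = list(stats[0].per_donor_values)
    rows = []
    for s in stats:
        row: dict[str, object] = {"gene_id": s.gene, "statistic": s.statistic_kind}
        for d in donor_ids:
            row[d] = _FLOAT_FMT % s.per_donor_values.get(d, math.nan)
        row["mean"] = _FLOAT_FMT % s.group_mean
        row["sd"] = _FLOAT_FMT % s.group_sd
        row["cv"] = _FLOAT_FMT % s.group_cv
        row["qualified"] = str(s.qualified)
        if differential is not None:
            r = differential.get(s.gene)
            row["log2_fc"] = _FLOAT_FMT % (r.log2_fc if r else math.nan)
            row["p_value"] = _FLOAT_FMT % (r.p_value if r else math.nan)
            row["significant"] = str(r.significant if r else False)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
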