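"""One-color microarray ratio analysis.

Implements the classic GeneSpring-style one-color workflow for small
intensity matrices, in a fixed order enforced by :func:`process_expression`:

1. floor raw intensities at 5.0,
2. divide each chip by its median (per-chip normalization, median → 1),
3. keep only probes flagged present (P) with intensity ≥ local background in
   every sample of the contrast,
4. average normalized intensities across replicates, aggregate probes to
   genes by mean,
5. fold change = mean(test)/mean(control) with its log2 ratio,
6. differential call: up if fold ≥ 2, down if fold ≤ 0.5 (both inclusive).

No multiple-testing machinery is attached: differential expression here is a
pure fold-change criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "IntensityMatrix",
    "Contrast",
    "floor_intensities",
    "per_chip_median_normalize",
    "filter_probes",
    "expression_ratio",
    "call_differential",
    "process_expression",
    "read_intensity_tsv",
    "write_intensity_tsv",
    "read_geo_series_matrix",
]

DEFAULT_FLOOR = 5.0
DEFAULT_UP = 2.0
DEFAULT_DOWN = 0.5

FLAGS = ("P", "M", "A")


@dataclass
class IntensityMatrix:
    """Raw or normalized one-color intensities for probes × samples.

    ``probes`` maps probe id → gene symbol; ``intensity``, ``background`` and
    ``flags`` are DataFrames indexed by probe id with sample-id columns;
    ``conditions`` maps sample id → condition label.
    """

    probes: pd.Series  # index: probe_id, values: gene symbol
    intensity: pd.DataFrame
    background: pd.DataFrame
    flags: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)
    normalized: bool = False

    def __post_init__(self) -> None:
        idx, cols = self.intensity.index, self.intensity.columns
        for name, df in (("background", self.background), ("flags", self.flags)):
            if not df.index.equals(idx) or not df.columns.equals(cols):
                raise ValueError(f"{name} matrix is not aligned with intensity")
        if not self.probes.index.equals(idx):
            raise ValueError("probe table is not aligned with intensity")
        bad = ~self.flags.isin(FLAGS)
        if bad.to_numpy().any():
            raise ValueError("flags must be one of P, M, A for every cell")

    @property
    def samples(self) -> list[str]:
        return list(self.intensity.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions.get(s) == condition]


@dataclass
class Contrast:
    """A test-vs-control comparison, e.g. stressed vs untreated cultures."""

    test: list[str]
    control: list[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.test or not self.control:
            raise ValueError("contrast groups must be non-empty")
        if set(self.test) & set(self.control):
            raise ValueError("contrast groups must be disjoint")

    @classmethod
    def from_conditions(
        cls, m: IntensityMatrix, test: str, control: str
    ) -> "Contrast":
        return cls(
            test=m.samples_for(test),
            control=m.samples_for(control),
            label=f"{test}/{control}",
        )

    @property
    def samples(self) -> list[str]:
        return self.test + self.control


def _copy_with(m: IntensityMatrix, intensity: pd.DataFrame, normalized=None) -> IntensityMatrix:
    return IntensityMatrix(
        probes=m.probes,
        intensity=intensity,
        background=m.background,
        flags=m.flags,
        conditions=dict(m.conditions),
        normalized=m.normalized if normalized is None else normalized,
    )


def floor_intensities(m: IntensityMatrix, floor: float = DEFAULT_FLOOR) -> IntensityMatrix:
    """Replace every intensity below *floor* by *floor* (default 5.0)."""
    if floor < 0:
        raise ValueError("floor must be non-negative")
    return _copy_with(m, m.intensity.clip(lower=floor))


def per_chip_median_normalize(m: IntensityMatrix) -> IntensityMatrix:
    """Divide each sample (chip) by its median intensity; median becomes 1."""
    medians = m.intensity.median(axis=0)
    if (medians == 0).any():
        zero = list(medians.index[medians == 0])
        raise ZeroDivisionError(f"zero median intensity in sample(s) {zero}")
    return _copy_with(m, m.intensity / medians, normalized=True)


def filter_probes(m: IntensityMatrix, contrast: Contrast) -> pd.Series:
    """Boolean mask of probes usable for *contrast*.

    A probe survives iff it is flagged P in every sample of the contrast and
    its intensity is at or above the local background in every sample.
    Filtering is mask-based; the matrix is left untouched.
    """
    samples = contrast.samples
    missing = [s for s in samples if s not in m.intensity.columns]
    if missing:
        raise KeyError(f"contrast samples not in matrix: {missing}")
    present = (m.flags[samples] == "P").all(axis=1)
    above_bg = (m.intensity[samples] >= m.background[samples]).all(axis=1)
    return present & above_bg


def expression_ratio(
    m: IntensityMatrix, contrast: Contrast, mask: pd.Series | None = None
) -> pd.DataFrame:
    """Per-gene fold changes for *contrast* on a normalized matrix.

    Replicates are averaged on normalized intensities before the ratio is
    formed; probes map to genes by arithmetic mean (one probe per gene on the
    platform emulated here, so usually the identity).  The fold is oriented
    test/control — stressed over unstressed — so an induction under stress
    yields fold > 1 and a positive log2 ratio.

    Returns a DataFrame with columns gene, mean_test, mean_control, fold,
    log2_ratio.
    """
    if not m.normalized:
        raise ValueError("expression_ratio expects a floored, normalized matrix")
    sub_int = m.intensity if mask is None else m.intensity.loc[mask]
    genes = m.probes if mask is None else m.probes.loc[mask]
    mean_test = sub_int[contrast.test].mean(axis=1)
    mean_control = sub_int[contrast.control].mean(axis=1)
    per_probe = pd.DataFrame(
        {"gene": genes, "mean_test": mean_test, "mean_control": mean_control}
    )
    per_gene = per_probe.groupby("gene", sort=True).mean()
    if (per_gene["mean_control"] <= 0).any():
        raise ZeroDivisionError("zero control mean; was the matrix floored?")
    out = per_gene.reset_index()
    out["fold"] = (per_gene["mean_test"] / per_gene["mean_control"]).to_numpy()
    # as a log-mean difference the ratio negates *exactly* under a swap of
    # test and control (log2(fold) only up to the last ulp)
    out["log2_ratio"] = np.log2(out["mean_test"].to_numpy()) - np.log2(
        out["mean_control"].to_numpy()
    )
    return out


def call_differential(
    records: pd.DataFrame, up: float = DEFAULT_UP, down: float = DEFAULT_DOWN
) -> pd.DataFrame:
    """Attach de_call: ``up`` iff fold ≥ up, ``down`` iff fold ≤ down, else ``none``."""
    if up <= down:
        raise ValueError("up threshold must exceed down threshold")
    out = records.copy()
    out["de_call"] = np.select(
        [out["fold"] >= up, out["fold"] <= down], ["up", "down"], default="none"
    )
    return out


def process_expression(
    m: IntensityMatrix,
    contrast: Contrast,
    floor: float = DEFAULT_FLOOR,
    up: float = DEFAULT_UP,
    down: float = DEFAULT_DOWN,
) -> pd.DataFrame:
    """Single entry point running the full pipeline in its fixed order:
    floor → per-chip median normalization → flag/background filter →
    replicate averaging → ratio → differential call."""
    floored = floor_intensities(m, floor)
    normalized = per_chip_median_normalize(floored)
    mask = filter_probes(floored, contrast)  # flags/background are pre-normalization data
    records = expression_ratio(normalized, contrast, mask)
    return call_differential(records, up=up, down=down)


# ---------------------------------------------------------------------------
# IO


def read_intensity_tsv(path, conditions: dict[str, str] | None = None) -> IntensityMatrix:
    """Read a long-format TSV: probe_id, gene, sample, intensity, background, flag.

    An optional ``condition`` column supplies the sample→condition mapping;
    a *conditions* dict argument overrides it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "gene": str, "sample": str})
    required = {"probe_id", "gene", "sample", "intensity", "background", "flag"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    intensity = df.pivot(index="probe_id", columns="sample", values="intensity")
    background = df.pivot(index="probe_id", columns="sample", values="background")
    flags = df.pivot(index="probe_id", columns="sample", values="flag")
    probes = df.drop_duplicates("probe_id").set_index("probe_id")["gene"]
    cond = conditions
    if cond is None and "condition" in df.columns:
        cond = (
            df.drop_duplicates("sample").set_index("sample")["condition"].to_dict()
        )
    return IntensityMatrix(
        probes=probes.reindex(intensity.index),
        intensity=intensity,
        background=background,
        flags=flags,
        conditions=cond or {},
    )


def write_intensity_tsv(m: IntensityMatrix, path) -> None:
    rows = []
    for sample in m.samples:
        chunk = pd.DataFrame(
            {
                "probe_id": m.intensity.index,
                "gene": m.probes.to_numpy(),
                "sample": sample,
                "intensity": m.intensity[sample].to_numpy(),
                "background": m.background[sample].to_numpy(),
                "flag": m.flags[sample].to_numpy(),
            }
        )
        if sample in m.conditions:
            chunk["condition"] = m.conditions[sample]
        rows.append(chunk)
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_geo_series_matrix(
    path, conditions: dict[str, str] | None = None
) -> IntensityMatrix:
    """Read a GEO series-matrix text file into an :class:`IntensityMatrix`.

    The series-matrix format carries one processed value per probe and
    sample between ``!series_matrix_table_begin`` and ``_end`` lines, with
    ``!Sample_geo_accession`` and ``!Sample_title`` metadata headers.  Flags
    and background are not part of the format; probes are marked P with zero
    background so that downstream filtering keeps every probe.  The
    sample→condition grouping must be supplied (via *conditions*, keyed by
    GEO accession or title) — it is deliberately not guessed.
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key, *values = line.split("\t")
                meta[key.lstrip("!")] = [v.strip('"') for v in values]
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix table found")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t")
    df.columns = [str(c).strip('"') for c in df.columns]
    probe_col = df.columns[0]
    df[probe_col] = df[probe_col].astype(str).str.strip('"')
    df = df.set_index(probe_col)
    intensity = df.astype(float)
    intensity.index.name = "probe_id"
    accessions = meta.get("Sample_geo_accession", list(intensity.columns))
    titles = meta.get("Sample_title", accessions)
    title_of = dict(zip(accessions, titles))
    cond: dict[str, str] = {}
    if conditions:
        for s in intensity.columns:
            if s in conditions:
                cond[s] = conditions[s]
            elif title_of.get(s) in conditions:
                cond[s] = conditions[title_of[s]]
    probes = pd.Series(intensity.index, index=intensity.index, name="gene")
    flags = pd.DataFrame("P", index=intensity.index, columns=intensity.columns)
    background = pd.DataFrame(0.0, index=intensity.index, columns=intensity.columns)
    return IntensityMatrix(
        probes=probes,
        intensity=intensity,
        background=background,
        flags=flags,
        conditions=cond,
    )
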