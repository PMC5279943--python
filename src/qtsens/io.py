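"""Shared readers/writers, packaged fixtures, configuration and reporting.

Tabular I/O uses TSV with ``#``-prefixed metadata header lines (tool version,
config hash, seed).  Gene intervals are BED-like, 0-based half-open.  Gene
sets use the GMT dialect.  Genotypes can round-trip through a minimal
VCF-like text format (CHROM, POS, ID, GT fields ``0/0``, ``0/1``, ``1/1``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import io as _io
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genetics import GenotypeMatrix
from .mea import BeatSeries

__all__ = [
    "PipelineConfig",
    "load_fixture",
    "fixture_names",
    "read_tsv",
    "write_tsv",
    "read_bed",
    "read_gmt",
    "write_beat_series_csv",
    "read_beat_series_csv",
    "write_genotypes_vcf",
    "read_genotypes_vcf",
    "run_report",
]

_FIXTURES = ("lines", "table1", "table3", "table5_pairs", "lqts_genes", "lqts_bed_synthetic")

# Group-mean maximal E4031 responses used to fill per-line responsiveness for
# responder lines when only the responder/non-responder status is known.
_E4031_GROUP_EMAX = {"high": 0.49, "low": 0.30}


@dataclasses.dataclass
class PipelineConfig:
    """Every tunable constant of the pipeline, with defaults.

    Unknown keys in a YAML config are rejected; the config is echoed into
    output headers so runs are self-describing.
    """

    seed: int = 0
    high_threshold_ms: float = 35.0
    low_threshold_ms: float = 5.0
    n_per_arm: int = 10
    power_diff_ms: float = 20.0
    power_sd_ms: float = 15.0
    power_alpha: float = 0.05
    classification_threshold: float = 0.25
    classification_concentration: float = 3e-5
    e4031_responsiveness_floor: float = 0.05
    arrhythmia_short_fraction: float = 0.8
    arrhythmia_cv_floor: float = 0.10
    arrhythmia_cv_factor: float = 2.0
    hill_h_min: float = 0.5
    hill_h_max: float = 4.0
    snp_alpha: float = 0.05
    deg_fdr: float = 0.05
    deg_min_fold: float = 1.3
    netto_zero_band: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _header_lines(config: PipelineConfig | None, seed: int | None) -> list[str]:
    lines = [f"# qtsens {__version__}"]
    if config is not None:
        lines.append(f"# config_hash {config.digest()}")
    if seed is not None:
        lines.append(f"# seed {seed}")
    return lines


def write_tsv(df: pd.DataFrame, path, config: PipelineConfig | None = None,
              seed: int | None = None, index: bool = False) -> None:
    """Write a DataFrame as TSV with ``#`` metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    path.write_text("\n".join(_header_lines(config, seed)) + "\n" + buf.getvalue())


def read_tsv(path, **kwargs) -> pd.DataFrame:
    """Read a TSV, skipping ``#`` metadata header lines."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_bed(path) -> pd.DataFrame:
    """Read BED-like intervals (chrom, start, end, gene); 0-based half-open."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "gene"],
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("BED intervals must satisfy start < end")
    return df


def read_gmt(path) -> dict:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets


def fixture_names() -> tuple:
    return _FIXTURES


def _fixture_path(filename: str):
    return resources.files("qtsens").joinpath("fixtures", filename)


def load_fixture(name: str):
    """Load a packaged fixture by name.

    Available: ``lines`` (17-line panel with groups, karyotype-derived gender,
    QC flags and per-line E4031 responsiveness), ``table1`` (baseline cohort
    characteristics), ``table3`` (25 imbalanced SNPs with per-group MAFs),
    ``table5_pairs`` (the 22 same-gender high/low pairs), ``lqts_genes`` (the
    15-gene seed list) and ``lqts_bed_synthetic`` (invented intervals for the
    panel, testing only).
    """
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: {', '.join(_FIXTURES)}")
    if name == "lqts_genes":
        text = _fixture_path("lqts15.txt").read_text()
        return tuple(line.strip() for line in text.splitlines() if line.strip())
    if name == "lqts_bed_synthetic":
        with resources.as_file(_fixture_path("lqts15_synthetic.bed")) as p:
            return read_bed(p)
    filename = {"lines": "lines.tsv", "table1": "table1.tsv",
                "table3": "table3.tsv", "table5_pairs": "table5_pairs.tsv"}[name]
    with resources.as_file(_fixture_path(filename)) as p:
        df = read_tsv(p)
    if name == "lines":
        df["karyotype_ok"] = df["karyotype_ok"].astype(bool)
        df["e4031_responder"] = df["e4031_responder"].astype(bool)
        df["e4031_max_change"] = [
            _E4031_GROUP_EMAX[g] if resp else 0.0
            for g, resp in zip(df["group"], df["e4031_responder"])
        ]
    return df


# ---------------------------------------------------------------------------
# generator output writers / readers


def write_cohort_tsv(records: pd.DataFrame, truth: pd.DataFrame, path,
                     config=None, seed=None) -> None:
    merged = records.merge(truth[["subject_id", "label"]], on="subject_id")
    write_tsv(merged, path, config=config, seed=seed)


def write_beat_series_csv(series_list, directory, config=None, seed=None) -> None:
    """One CSV per line: beat_index, IBI_ms, rawFPD_ms, concentration_M."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_line = {}
    for s in series_list:
        by_line.setdefault(s.line_id, []).append(s)
    for line_id, group in by_line.items():
        frames = []
        for s in sorted(group, key=lambda s: s.concentration):
            frames.append(
                pd.DataFrame(
                    {
                        "beat_index": np.arange(s.ibi.size),
                        "IBI_ms": s.ibi,
                        "rawFPD_ms": s.raw_fpd,
                        "concentration_M": s.concentration,
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        out = directory / f"{line_id}.csv"
        buf = _io.StringIO()
        df.to_csv(buf, index=False)
        out.write_text("\n".join(_header_lines(config, seed)) + "\n" + buf.getvalue())


def read_beat_series_csv(path) -> list:
    """Read one line's CSV back into a list of BeatSeries (one per concentration)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    line_id = path.stem
    out = []
    for c, sub in df.groupby("concentration_M", sort=True):
        out.append(
            BeatSeries(
                line_id=line_id,
                concentration=float(c),
                ibi=sub["IBI_ms"].to_numpy(),
                raw_fpd=sub["rawFPD_ms"].to_numpy(),
            )
        )
    return out


_GT = {0: "0/0", 1: "0/1", 2: "1/1"}
_GT_INV = {v: k for k, v in _GT.items()} | {"./.": np.nan}


def write_genotypes_vcf(matrix: GenotypeMatrix, path) -> None:
    """Minimal VCF-like export: CHROM, POS, ID then one GT column per subject."""
    path = Path(path)
    subjects = list(matrix.dosage.index)
    lines = ["#CHROM\tPOS\tID\t" + "\t".join(subjects)]
    for snp in matrix.dosage.columns:
        info = matrix.snp_info.loc[snp]
        chrom = info.get("chrom", ".")
        pos = info.get("pos", 0)
        gts = []
        for s in subjects:
            d = matrix.dosage.loc[s, snp]
            gts.append("./." if pd.isna(d) else _GT[int(d)])
        lines.append(f"{chrom}\t{pos}\t{snp}\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")


def read_genotypes_vcf(path, groups: pd.Series) -> GenotypeMatrix:
    lines = Path(path).read_text().splitlines()
    header = lines[0].lstrip("#").split("\t")
    subjects = header[3:]
    dosage = {}
    info = []
    for line in lines[1:]:
        chrom, pos, snp, *gts = line.split("\t")
        dosage[snp] = [_GT_INV[g] for g in gts]
        info.append({"snp_id": snp, "chrom": chrom, "pos": int(pos)})
    return GenotypeMatrix(
        dosage=pd.DataFrame(dosage, index=subjects, dtype=float),
        snp_info=pd.DataFrame(info).set_index("snp_id"),
        groups=pd.Series(groups),
    )


def run_report(stage_outputs: dict, out_path, config: PipelineConfig | None = None,
               seed: int | None = None, required=()) -> dict:
    """Assemble per-stage outputs into one JSON report.

    ``stage_outputs`` maps stage name → DataFrame / dict / scalar.  Stages in
    ``required`` that are absent raise (the CLI maps this to a nonzero exit).
    Output ordering is deterministic so reruns under a fixed seed are
    byte-identical.
    """
    missing = [s for s in required if s not in stage_outputs]
    if missing:
        raise ValueError(f"missing stages: {missing}")
    report = {
        "tool": f"qtsens {__version__}",
        "config": config.to_dict() if config else None,
        "config_hash": config.digest() if config else None,
        "seed": seed,
        "stages": {},
    }
    for name in sorted(stage_outputs):
        val = stage_outputs[name]
        if isinstance(val, pd.DataFrame):
            val = json.loads(val.to_json(orient="split"))
        elif isinstance(val, pd.Series):
            val = val.to_dict()
        report["stages"][name] = val
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    out_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str) + "\n")
    return report
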