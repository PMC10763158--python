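"""End-to-end orchestration: QC -> diversity -> ROH -> islands -> FST ->
distances/MDS, with TSV report tables and a machine-readable run manifest.

Every stage is a thin call into the library modules; the pipeline only
sequences them, writes outputs and records what it did.  All analysis
stages are deterministic; the only randomness (simulation) flows from the
config seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dataset import Dataset
from .diversity import diversity_table
from .plinkio import read_plink
from .popstruct import classical_mds, ibs_distance, reynolds_distance
from .qc import qc_filter
from .roh import L_AUT_MB, RohParams, detect_roh_all, froh_table
from .selection import (
    build_contrasts,
    fst_scan,
    roh_islands,
    snp_roh_frequency,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; serializable to JSON."""

    input_prefix: str
    out_dir: str
    dialect: str = "binary"
    group_map: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    # QC
    snp_call_rate: float = 0.90
    maf_min: float = 0.05
    ind_max_missing: float = 0.10
    # ROH criteria
    roh: RohParams = field(default_factory=RohParams)
    l_aut_mb: float = L_AUT_MB
    # selection scan
    island_top_fraction: float = 0.001
    fst_window_kb: float = 500.0
    fst_step_kb: float = 250.0
    fst_min_snps: int = 5
    fst_top_fraction: float = 0.0005
    # population structure
    mds_dimensions: int = 2

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        raw = json.loads(text)
        raw["roh"] = RohParams(**raw.get("roh", {}))
        return cls(**raw)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    # full float repr: stage-by-stage and run-all outputs stay byte-identical
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: RunConfig, ds: Dataset | None = None) -> dict:
    """Run the full workflow and write the report bundle to ``out_dir``.

    Returns the manifest dict (also written as ``manifest.json``).  Stages
    needing at least two populations (FST, distances) are skipped with a
    logged reason on single-population data.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": json.loads(config.to_json()),
        "stages": {},
    }
    stage = "read"
    try:
        if ds is None:
            ds = read_plink(config.input_prefix, config.dialect, config.group_map)
        elif config.group_map:
            ds = ds.with_groups(config.group_map)
        manifest["stages"]["read"] = {
            "n_samples": ds.n_samples,
            "n_variants": ds.n_variants,
        }

        stage = "qc"
        ds, qc_report = qc_filter(
            ds, config.snp_call_rate, config.maf_min, config.ind_max_missing
        )
        qc_report.to_tsv(out / "qc_report.tsv")
        manifest["stages"]["qc"] = {
            "n_snps_removed_callrate": qc_report.n_snps_removed_callrate,
            "n_snps_removed_maf": qc_report.n_snps_removed_maf,
            "n_samples_removed_missing": qc_report.n_samples_removed_missing,
            "n_snps_out": qc_report.n_snps_out,
            "n_samples_out": qc_report.n_samples_out,
        }

        stage = "diversity"
        div = diversity_table(ds)

        stage = "roh"
        segments = detect_roh_all(ds, config.roh)
        _write_tsv(segments, out / "roh_segments.tsv")
        ind_froh, breed_froh = froh_table(ds, segments, config.l_aut_mb)
        _write_tsv(ind_froh, out / "froh_individual.tsv")
        _write_tsv(breed_froh, out / "froh_breed.tsv")
        div = div.merge(
            breed_froh.rename(columns={"f_roh": "f_roh"}), on="population", how="left"
        )
        _write_tsv(div, out / "diversity.tsv")
        manifest["stages"]["roh"] = {"n_segments": int(len(segments))}

        stage = "roh_islands"
        freq_frames, island_frames = [], []
        for pop in ds.populations:
            freqs = snp_roh_frequency(segments, ds, pop)
            freq_frames.append(freqs)
            island_frames.append(roh_islands(freqs, config.island_top_fraction))
        _write_tsv(pd.concat(freq_frames, ignore_index=True), out / "roh_occurrence.tsv")
        non_empty = [f for f in island_frames if len(f)]
        islands = (
            pd.concat(non_empty, ignore_index=True) if non_empty else island_frames[0]
        )
        _write_tsv(islands, out / "roh_islands.tsv")
        manifest["stages"]["roh_islands"] = {"n_islands": int(len(islands))}

        n_pops = len(ds.populations)
        groups = set(ds.samples["group"]) - {"none"}
        if n_pops >= 2 and {"wet", "dry"} <= groups:
            stage = "fst_scan"
            contrasts = build_contrasts(ds)
            windows, significant = fst_scan(
                ds,
                config.fst_window_kb,
                config.fst_step_kb,
                config.fst_min_snps,
                config.fst_top_fraction,
                contrasts,
            )
            _write_tsv(windows, out / "fst_windows.tsv")
            _write_tsv(significant, out / "fst_significant.tsv")
            manifest["stages"]["fst_scan"] = {
                "contrasts": [c.label for c in contrasts],
                "n_windows": int(len(windows)),
                "n_significant": int(len(significant)),
            }
        else:
            logger.info(
                "FST scan skipped: needs >= 2 populations with wet and dry groups"
            )
            manifest["stages"]["fst_scan"] = {
                "skipped": "needs >= 2 populations with wet and dry groups"
            }

        if n_pops >= 2:
            stage = "distances"
            reyn = reynolds_distance(ds)
            reyn.to_phylip(out / "reynolds.phy")
            reyn.to_nexus(out / "reynolds.nex")
            ibs = ibs_distance(ds)
            ibs.to_phylip(out / "ibs.phy")
            stage = "mds"
            mds = classical_mds(ibs, config.mds_dimensions)
            mds.to_tsv(out / "mds_coordinates.tsv")
            manifest["stages"]["mds"] = {
                "variance_explained": [float(v) for v in mds.variance_explained]
            }
        else:
            logger.info("distance/MDS stages skipped: single population")
            manifest["stages"]["distances"] = {"skipped": "single population"}
    except Exception as exc:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
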