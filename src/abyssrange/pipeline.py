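"""Stage orchestration: records -> popgen -> distances -> network ->
delimitation -> habitat, with a reproducible run manifest."""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .alignment import collapse_haplotypes, complete_deletion, read_alignment, write_haplotype_csv
from .delimit import best_partition, linkage_sweep, write_membership_csv, write_sweep_csv
from .distances import (
    BaseFrequencies,
    correct_distances,
    distance_range,
    p_distance_matrix,
    write_long_csv,
    write_matrix_csv,
)
from .errors import ConfigurationError, StageError
from .habitat import habitat_report, read_bathymetry_netcdf, write_report_csv
from .network import build_network, classify_haplotypes, connection_limit, write_edge_csv, write_graphml
from .popgen import diversity_summary
from .records import DepthEnvelope, envelope_from_records, read_records, summarize_records

log = logging.getLogger("abyssrange")

STAGES = ("records", "popgen", "distances", "network", "delimitation", "habitat")


@dataclass
class RunConfig:
    """Validated options for one pipeline run."""

    output_dir: Path
    records_path: Path | None = None
    alignment_path: Path | None = None
    locus: str = "other"
    locality_path: Path | None = None  # CSV: id,locality
    bathymetry_path: Path | None = None  # netCDF with elevation + basin_code
    deletion_mode: str = "complete"
    distance_model: str = "JC69"  # JC69 | F81
    base_frequencies: BaseFrequencies | None = None
    network_threshold: float = 0.95
    mc_reps: int = 10000
    seed: int = 0
    envelope: DepthEnvelope | None = None  # override; else derived from records
    stages: tuple[str, ...] = STAGES

    def validate(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ConfigurationError(f"unknown stage {s!r}")
        genetic = {"popgen", "distances", "network", "delimitation"} & set(self.stages)
        if genetic and self.alignment_path is None:
            raise ConfigurationError(
                f"stages {sorted(genetic)} require an alignment path"
            )
        if "records" in self.stages and self.records_path is None:
            raise ConfigurationError("records stage requires a records path")
        if "habitat" in self.stages:
            if self.bathymetry_path is None:
                raise ConfigurationError("habitat stage requires a bathymetry path")
            if self.envelope is None and self.records_path is None:
                raise ConfigurationError(
                    "habitat stage needs an envelope override or a records path"
                )
        if self.distance_model == "F81" and self.base_frequencies is None:
            raise ConfigurationError("F81 distances require base frequencies")
        for p in (self.records_path, self.alignment_path, self.locality_path,
                  self.bathymetry_path):
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"input path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        paths = {"output_dir", "records_path", "alignment_path", "locality_path",
                 "bathymetry_path"}
        for key, value in raw.items():
            if key == "base_frequencies" and value is not None:
                kwargs[key] = BaseFrequencies(*[float(v) for v in value])
            elif key == "envelope" and value is not None:
                kwargs[key] = DepthEnvelope(float(value[0]), float(value[1]))
            elif key == "stages" and value is not None:
                kwargs[key] = tuple(value)
            elif key in paths and value is not None:
                kwargs[key] = Path(value)
            else:
                kwargs[key] = value
        if "output_dir" not in kwargs:
            raise ConfigurationError("config must set output_dir")
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_locality_csv(path: Path) -> dict[str, str]:
    out = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out[row["id"]] = row["locality"]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write a JSON run manifest.

    Returns the manifest dict.  Any stage failure is re-raised as a
    :class:`StageError` naming the stage.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in (
                ("records", config.records_path),
                ("alignment", config.alignment_path),
                ("locality", config.locality_path),
                ("bathymetry", config.bathymetry_path),
            )
            if p is not None
        },
        "stages": {},
    }

    state: dict = {}

    def stage(name, fn):
        if name not in config.stages:
            return
        t0 = time.perf_counter()
        log.info("stage %s: starting", name)
        try:
            outputs = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
        manifest["stages"][name] = {
            "outputs": [str(o) for o in outputs],
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)

    def records_stage():
        recs = read_records(config.records_path)
        state["records"] = recs
        summary = summarize_records(recs)
        state["envelope"] = config.envelope or envelope_from_records(recs)
        path = outdir / "record_summary.json"
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "n_records": summary.n_records,
                    "n_sites": summary.n_sites,
                    "depth_min_m": summary.depth_min_m,
                    "depth_max_m": summary.depth_max_m,
                    "counts_per_feature": summary.counts_per_feature,
                    "counts_per_basin": summary.counts_per_basin,
                },
                fh,
                indent=2,
            )
        log.info("records: %d records at %d sites", summary.n_records, summary.n_sites)
        return [path]

    def load_alignment():
        if "alignment" not in state:
            locality = (
                _read_locality_csv(config.locality_path)
                if config.locality_path
                else None
            )
            aln = read_alignment(config.alignment_path, locus=config.locus,
                                 locality_map=locality)
            state["alignment"] = aln
            state["filter"] = complete_deletion(aln)
            state["table"] = collapse_haplotypes(aln, state["filter"])
        return state["alignment"], state["filter"], state["table"]

    def popgen_stage():
        aln, sf, table = load_alignment()
        stats = diversity_summary(aln, sf, table)
        raw = p_distance_matrix(aln, config.deletion_mode, site_filter=sf
                                if config.deletion_mode == "complete" else None)
        corrected = correct_distances(raw, config.distance_model,
                                      config.base_frequencies)
        lo, hi = distance_range(corrected)
        path = outdir / "diversity_stats.csv"
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["locus", "n", "H", "h", "pi", "ss", "k_hat",
                        "distance_min", "distance_max", "tajimas_D", "p_value",
                        "stars"])
            w.writerow([aln.locus, stats.n, stats.H, f"{stats.h:.5f}",
                        f"{stats.pi:.5f}", stats.ss, f"{stats.k_hat:.5f}",
                        f"{lo:.5f}", f"{hi:.5f}", f"{stats.D:.5f}",
                        f"{stats.p_value:.5g}", stats.stars])
        hpath = outdir / "haplotypes.csv"
        write_haplotype_csv(table, hpath)
        return [path, hpath]

    def distances_stage():
        aln, sf, _ = load_alignment()
        raw = p_distance_matrix(aln, config.deletion_mode, site_filter=sf
                                if config.deletion_mode == "complete" else None)
        corrected = correct_distances(raw, config.distance_model,
                                      config.base_frequencies)
        state["distance_matrix"] = corrected
        p1 = outdir / "distances_raw.csv"
        p2 = outdir / f"distances_{config.distance_model.lower()}.csv"
        p3 = outdir / "distances_long.csv"
        write_matrix_csv(raw, p1)
        write_matrix_csv(corrected, p2)
        write_long_csv(corrected, p3)
        return [p1, p2, p3]

    def network_stage():
        aln, sf, table = load_alignment()
        limit = connection_limit(sf.L_retained, threshold=config.network_threshold,
                                 mc_reps=config.mc_reps, seed=config.seed)
        g = build_network(table, limit)
        classes = classify_haplotypes(table) if aln.locality else {}
        p1 = outdir / "network.graphml"
        p2 = outdir / "network_edges.csv"
        write_graphml(g, p1)
        write_edge_csv(g, p2)
        p3 = outdir / "haplotype_classes.json"
        with open(p3, "w", encoding="utf-8") as fh:
            json.dump({"connection_limit": limit, "classes": classes}, fh, indent=2)
        return [p1, p2, p3]

    def delimitation_stage():
        aln, sf, _ = load_alignment()
        if "distance_matrix" not in state:
            raw = p_distance_matrix(aln, "complete", site_filter=sf)
            state["distance_matrix"] = correct_distances(
                raw, config.distance_model, config.base_frequencies
            )
        sweep = linkage_sweep(state["distance_matrix"])
        top, ranked = best_partition(sweep)
        p1 = outdir / "partition_sweep.csv"
        p2 = outdir / "partition_membership.csv"
        write_sweep_csv(sweep, ranked, p1)
        write_membership_csv(top.partition, p2)
        if top.no_gap_warning:
            log.warning("delimitation: no positive barcode gap; one group returned")
        return [p1, p2]

    def habitat_stage():
        envelope = config.envelope or state.get("envelope")
        if envelope is None:
            recs = read_records(config.records_path)
            envelope = envelope_from_records(recs)
        grid, mask = read_bathymetry_netcdf(config.bathymetry_path)
        if mask is None:
            raise ConfigurationError("bathymetry file lacks a basin_code variable")
        report = habitat_report(grid, mask, envelope)
        path = outdir / "habitat_report.csv"
        write_report_csv(report, path)
        log.info("habitat: global percent %s", report.global_percent)
        return [path]

    stage("records", records_stage)
    stage("popgen", popgen_stage)
    stage("distances", distances_stage)
    stage("network", network_stage)
    stage("delimitation", delimitation_stage)
    stage("habitat", habitat_stage)

    mpath = outdir / "manifest.json"
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
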