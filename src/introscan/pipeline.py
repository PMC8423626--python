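"""End-to-end orchestration: simulate -> filter -> diversity -> D/f_d ->
IBD/rIBD -> segments/proportions, with a checksummed run manifest and
stage-level caching.

Configuration is a flat YAML file; command-line flags override file values,
which override defaults.  All randomness flows from the single ``seed``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import diversity as div
from . import introgression as intro
from .popsim import simulate_panel
from .popsim.presets import demo_demography, demo_genome, demo_noise
from .variants import (FilterSpec, filter_variants, make_windows, read_vcf,
                       write_vcf)

logger = logging.getLogger(__name__)

DEFAULTS: dict[str, Any] = {
    "seed": 1,
    "outdir": "introscan_run",
    # inputs; when absent the bundled simulator provides them
    "vcf": None,
    "panel": None,
    # stage toggles
    "run_simulate": True,
    "run_filter": True,
    "run_diversity": True,
    "run_dstat": True,
    "run_fd": True,
    "run_ribd": True,
    # simulator scenario
    "pulse_proportion": 0.15,
    "pulse_generation": 50,
    # filters
    "min_depth": 4, "min_gq": 5, "min_maf": 0.05,
    "max_missing": 0.1, "max_het": 0.1,
    # windows
    "window_size": 10_000, "window_step": 5_000,
    # roles / groups
    "p1": "G5", "p2": "G4", "p3": "G2", "outgroup": "OUT",
    "target": "G4", "donor": "G2", "source": "G5",
    # statistics parameters
    "fd_window_snps": 100,
    "jackknife_block_snps": 500,
    "ibd_min_snps": 50, "ibd_min_bp": 100_000, "ibd_max_mismatch": 1,
    "ribd_threshold": 0.7,
}


@dataclass
class RunConfig:
    values: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        unknown = set(self.values) - set(DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        merged = dict(DEFAULTS)
        merged.update({k: v for k, v in self.values.items() if v is not None})
        self.values = merged

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        vals: dict[str, Any] = {}
        if path is not None:
            with open(path) as fh:
                vals.update(yaml.safe_load(fh) or {})
        vals.update({k: v for k, v in overrides.items() if v is not None})
        return cls(vals)

    def __getitem__(self, key: str):
        return self.values[key]

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.values, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    stages: dict[str, dict] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "stages": self.stages},
                      fh, indent=2, sort_keys=True)

    @classmethod
    def read(cls, path: Path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(config_hash=d["config_hash"], stages=d["stages"])


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order, reusing cached stage
    outputs when the stage's config and input checksums are unchanged.

    A stage failure raises :class:`StageError` naming the stage; downstream
    outputs are not written.
    """
    out = Path(config["outdir"])
    out.mkdir(parents=True, exist_ok=True)
    logger.info("run config: %s", json.dumps(config.values, sort_keys=True,
                                             default=str))
    manifest = RunManifest(config_hash=config.hash())
    prev = None
    mpath = out / "manifest.json"
    if mpath.exists():
        try:
            prev = RunManifest.read(mpath)
        except Exception:
            prev = None

    def run_stage(name: str, inputs: list[Path], outputs: list[Path], fn):
        t0 = time.time()
        key = hashlib.sha256(json.dumps(
            [config.hash()] + [_sha256(p) for p in inputs], default=str
        ).encode()).hexdigest()[:16]
        cached = (prev is not None and name in prev.stages
                  and prev.stages[name].get("key") == key
                  and all(p.exists() for p in outputs))
        if cached:
            logger.info("[%s] cached, reusing outputs", name)
            manifest.stages[name] = dict(prev.stages[name], cached=True)
            return
        logger.info("[%s] running", name)
        try:
            counts = fn() or {}
        except Exception as e:  # noqa: BLE001 - halt with the failing stage named
            raise StageError(name, e) from e
        manifest.stages[name] = {
            "key": key,
            "inputs": {str(p): _sha256(p) for p in inputs},
            "outputs": {str(p): _sha256(p) for p in outputs},
            "counts": counts,
            "seconds": round(time.time() - t0, 3),
            "cached": False,
        }

    vcf_path = Path(config["vcf"]) if config["vcf"] else out / "sim.vcf"
    panel_path = Path(config["panel"]) if config["panel"] else out / "panel.tsv"

    if config["run_simulate"] and config["vcf"] is None:
        def _simulate():
            dem = demo_demography(config["pulse_proportion"],
                                  config["pulse_generation"])
            m, panel, truth = simulate_panel(dem, demo_genome(), demo_noise(),
                                             seed=config["seed"])
            write_vcf(m, vcf_path)
            panel.role = {s: r for s, g in panel.group.items()
                          for lbl, r in {"G5": "P1", "G4": "P2", "G2": "P3",
                                         "OUT": "outgroup"}.items() if g == lbl}
            panel.write(panel_path)
            truth.write(out / "truth.tsv")
            return {"samples": m.n_samples, "sites": m.n_sites}
        run_stage("simulate", [], [vcf_path, panel_path], _simulate)
    for p in (vcf_path, panel_path):
        if not p.exists():
            raise FileNotFoundError(f"required input {p} does not exist")

    filtered_vcf = out / "filtered.vcf"
    if config["run_filter"]:
        def _filter():
            m, panel = read_vcf(vcf_path, panel_path)
            spec = FilterSpec(config["min_depth"], config["min_gq"],
                              config["min_maf"], config["max_missing"],
                              config["max_het"])
            kept, rep = filter_variants(m, spec)
            write_vcf(kept, filtered_vcf)
            _csv(rep.to_frame(), out / "filter_report.tsv")
            return {"sites_in": rep.n_in, "sites_out": rep.n_out}
        run_stage("filter", [vcf_path, panel_path], [filtered_vcf], _filter)
    analysis_vcf = filtered_vcf if config["run_filter"] else vcf_path

    def _load():
        return read_vcf(analysis_vcf, panel_path)

    if config["run_diversity"]:
        def _diversity():
            m, panel = _load()
            windows = make_windows(m.contigs, config["window_size"],
                                   config["window_step"])
            groups = sorted(set(panel.group.values()))
            frames = []
            for g in groups:
                f = div.windowed_pi(m, panel, g, windows)
                f.insert(0, "group", g)
                frames.append(f)
            _csv(pd.concat(frames), out / "pi.tsv")
            rows = []
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    _, fst = div.weir_cockerham_fst(m, panel, groups[i], groups[j])
                    rows.append((groups[i], groups[j], fst))
            _csv(pd.DataFrame(rows, columns=["group_a", "group_b", "fst"]),
                 out / "fst.tsv")
            return {"groups": len(groups)}
        run_stage("diversity", [analysis_vcf], [out / "pi.tsv", out / "fst.tsv"],
                  _diversity)

    if config["run_dstat"]:
        def _dstat():
            m, panel = _load()
            st = intro.patterson_d(m, panel, config["p1"], config["p2"],
                                   config["p3"], config["outgroup"],
                                   block_size=config["jackknife_block_snps"])
            _csv(pd.DataFrame([{"p1": config["p1"], "p2": config["p2"],
                                "p3": config["p3"], "outgroup": config["outgroup"],
                                "d": st.d, "se": st.se, "z": st.z,
                                "n_sites": st.n_sites,
                                "n_blocks": st.n_blocks}]),
                 out / "dstat.tsv")
            return {"d": round(st.d, 4), "z": round(st.z, 2)}
        run_stage("dstat", [analysis_vcf], [out / "dstat.tsv"], _dstat)

    if config["run_fd"]:
        def _fd():
            m, panel = _load()
            f = intro.fd_windows(m, panel, config["p1"], config["p2"],
                                 config["p3"], config["outgroup"],
                                 window_snps=config["fd_window_snps"])
            _csv(f, out / "fd.tsv")
            return {"windows": len(f)}
        run_stage("fd", [analysis_vcf], [out / "fd.tsv"], _fd)

    if config["run_ribd"]:
        def _ribd():
            m, panel = _load()
            for g in (config["target"], config["donor"], config["source"]):
                panel.samples_in_group(g)  # raises naming the missing group
            dpairs = intro.group_hap_pairs(m, panel, config["target"],
                                           config["donor"])
            spairs = intro.group_hap_pairs(m, panel, config["target"],
                                           config["source"])
            kw = dict(min_snps=config["ibd_min_snps"],
                      min_bp=config["ibd_min_bp"],
                      max_mismatch=config["ibd_max_mismatch"])
            dt = intro.detect_ibd(m, dpairs, **kw)
            st = intro.detect_ibd(m, spairs, **kw)
            _csv(dt, out / "ibd_donor.tsv")
            _csv(st, out / "ibd_source.tsv")
            prof = intro.ribd_scan(dt, st, panel, config["target"],
                                   config["donor"], config["source"],
                                   m.contigs, config["window_size"],
                                   config["window_step"])
            _csv(prof.bins, out / "ribd.tsv")
            segs = intro.call_segments(prof, config["ribd_threshold"],
                                       donor_tracts=dt)
            seg_bed = segs.drop(columns=["carriers"], errors="ignore")
            seg_bed.to_csv(out / "segments.bed", sep="\t", index=False,
                           header=False)
            prop = intro.introgressed_proportion(dt, panel, config["target"],
                                                 m.contigs)
            prop.rename_axis("sample").reset_index().to_csv(
                out / "proportions.tsv", sep="\t", index=False,
                float_format="%.10g")
            return {"donor_tracts": len(dt), "source_tracts": len(st),
                    "segments": len(segs),
                    "mean_proportion": round(float(prop.mean()), 4)}
        run_stage("ribd", [analysis_vcf],
                  [out / "ribd.tsv", out / "segments.bed",
                   out / "proportions.tsv"], _ribd)

    manifest.write(mpath)
    logger.info("pipeline complete; manifest at %s", mpath)
    return manifest
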