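"""End-to-end sweep-scan pipeline.

Chains the full analysis on one locus alignment: per-population summary
statistics, sliding-window profiles, pairwise F_st, the haplotype-
homogeneity test at a focal indel, and the CLR sweep scan with its
simulation-calibrated threshold. Results land as TSV files plus a JSON
manifest recording seeds, model names and thresholds; any stage failure
aborts with an error naming the stage, leaving earlier outputs and a
failure marker in place.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .alignment import (
    classify_sites,
    indel_events,
    partition_by_indel,
    read_alignment,
    site_table,
)
from .clr import ClrSweepScan, background_sfs, calibrate_threshold
from .coalescent import DemographicModel
from .datasets import demographic_model
from .hht import HudsonHaplotypeTest
from .popstats import WindowSpec, hudson_fst, sliding_windows, summary_stats

log = logging.getLogger("indelsweep")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    ``fasta``/``pop_map`` name the inputs; ``model`` is a named
    demographic model ("constant", "duchen", "werzner",
    "thornton-andolfatto") or a path to a model YAML; Monte Carlo sizes
    downscale through ``reps``.
    """

    fasta: str
    out_dir: str
    pop_map: str | None = None
    outgroup_fasta: str | None = None
    window: int = 500
    step: int = 250
    grid_spacing: float = 1000.0
    model: str = "constant"
    rho: float = 0.0
    reps: int = 1000
    seed: int = 0
    indel_span: tuple[int, int] | None = None
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "indel_span" in data and data["indel_span"] is not None:
            data["indel_span"] = tuple(data["indel_span"])
        return cls(**data)

    def resolve_model(self) -> DemographicModel:
        if Path(self.model).suffix in (".yml", ".yaml"):
            return DemographicModel.from_yaml(self.model)
        return demographic_model(self.model)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis; returns the manifest dictionary."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "model": cfg.model,
        "reps": cfg.reps,
        "stages": {},
    }
    marker = out / "INCOMPLETE"
    marker.write_text("run in progress\n")

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            log.info("stage %s ...", name)
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name] = {"seconds": round(time.time() - t0, 2)}
            return result

        return wrap

    aln = stage("read")(lambda: read_alignment(cfg.fasta, cfg.pop_map))
    outgroups = (
        stage("read-outgroups")(lambda: read_alignment(cfg.outgroup_fasta))
        if cfg.outgroup_fasta
        else None
    )
    records = stage("classify")(lambda: classify_sites(aln, outgroups))
    site_table(records).to_csv(out / "sites.tsv", sep="\t", index=False)

    def _stats():
        rows = []
        for pop in aln.populations:
            sub = aln.by_population(pop)
            st = summary_stats(sub)
            rows.append({"population": pop, **st.to_dict()})
        import pandas as pd

        return pd.DataFrame(rows)

    stats_df = stage("stats")(_stats)
    stats_df.to_csv(out / "summary_stats.tsv", sep="\t", index=False)

    pops = aln.populations
    pairs = [(a, b) for i, a in enumerate(pops) for b in pops[i + 1 :]]

    def _windows():
        return sliding_windows(
            aln, WindowSpec(cfg.window, cfg.step), fst_pairs=pairs
        )

    windows_df = stage("windows")(_windows)
    windows_df.to_csv(out / "windows.tsv", sep="\t", index=False)

    def _fst():
        import pandas as pd

        rows = []
        for a, b in pairs:
            res = hudson_fst(aln, a, b)
            rows.append(
                {"pop_a": a, "pop_b": b, "hw": res.hw, "hb": res.hb, "fst": res.fst}
            )
        return pd.DataFrame(rows)

    if pairs:
        stage("fst")(_fst).to_csv(out / "fst.tsv", sep="\t", index=False)

    model = cfg.resolve_model()

    # haplotype test at the focal indel (auto-detected if not configured)
    span = cfg.indel_span
    if span is None:
        events = indel_events(records)
        if events:
            span = max(events, key=lambda ev: ev[1] - ev[0])
    if span is not None:
        def _hht():
            part = partition_by_indel(aln, span)
            carriers = part.carriers
            if len(carriers) < 2 or len(carriers) == aln.n:
                return None
            sub = aln.subset(carriers)
            from .popstats import segregating_sites

            s_total, _ = segregating_sites(aln)
            s_sub, _ = segregating_sites(sub)
            res = HudsonHaplotypeTest(
                aln.n, s_total, len(carriers), s_sub, model=model
            ).fit(reps=cfg.reps, seed=cfg.seed)
            (out / "hht.txt").write_text(res.summary() + "\n")
            return {
                "p_value": res.p_value,
                "carriers": len(carriers),
                "S_total": s_total,
                "carrier_S": s_sub,
            }

        hht_info = stage("hht")(_hht)
        if hht_info:
            manifest["hht"] = hht_info

    def _scan():
        n = aln.n
        usable = [r for r in records if r.kind in ("snp", "invariant")]
        counts, positions = [], []
        for r in usable:
            if isinstance(r.derived_count, int):
                c = r.derived_count
            else:  # unpolarized: fall back to minor count
                from collections import Counter

                states = Counter(aln.column(r.column))
                c = min(states.values()) if len(states) > 1 else 0
            if r.n_called == n:
                counts.append(c)
                positions.append(r.column)
        bg = background_sfs(counts, n)
        scan = ClrSweepScan(
            np.asarray(positions, float),
            np.asarray(counts, int),
            bg,
            grid_spacing=cfg.grid_spacing,
            span=(1.0, float(aln.length)),
        )
        theta_hat = max(
            sum(1 for c in counts if 0 < c < n)
            / sum(1.0 / i for i in range(1, n)),
            1.0,
        )
        cal = calibrate_threshold(
            bg,
            model=model,
            locus_length=float(aln.length),
            rho=cfg.rho,
            theta=theta_hat,
            reps=max(cfg.reps, 100),
            seed=cfg.seed,
            grid_spacing=cfg.grid_spacing,
        )
        return scan.fit(threshold=cal.threshold), cal

    scan_res, cal = stage("clr")(_scan)
    scan_res.table.to_csv(out / "clr_scan.tsv", sep="\t", index=False)
    manifest["clr"] = {
        "threshold_5pct": cal.threshold,
        "peak_position": scan_res.peak_position,
        "peak_lambda": scan_res.max_lambda,
        "significant": bool(scan_res.max_lambda > cal.threshold),
    }

    if cfg.make_plots:
        def _plots():
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            fig, axes = plt.subplots(2, 1, figsize=(8, 6), sharex=True)
            axes[0].plot(windows_df["start"], windows_df["theta_w"], "o-", ms=3)
            axes[0].set_ylabel("Watterson theta /100 sites")
            scan_res.plot(ax=axes[1])
            fig.tight_layout()
            fig.savefig(out / "profiles.png", dpi=150)
            plt.close(fig)

        stage("plots")(_plots)

    manifest["outputs"] = {
        p.name: _sha256(p) for p in sorted(out.iterdir()) if p.is_file() and p.name != "INCOMPLETE"
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    marker.unlink(missing_ok=True)
    return manifest
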