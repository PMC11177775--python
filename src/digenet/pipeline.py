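"""End-to-end orchestration: trend screen -> pair scan -> network test.

Every stage writes its TSV into the output directory together with a
``manifest.json`` recording parameters, input checksums, per-stage seeds
and the package version, so a run can be reproduced byte-for-byte.  All
randomness derives from one user seed, expanded deterministically into one
child seed per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortData
from .network import DigenicNetworkTest, connectivity_curve
from .plink import read_map, read_ped, write_pattern_list
from .scan import DigenicScan
from .trend import TrendScreen

logger = logging.getLogger(__name__)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def stage_seeds(seed: int, n: int = 3) -> list[int]:
    """Deterministically expand one user seed into per-stage seeds (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(
    ped: str | Path,
    map_file: str | Path,
    out_dir: str | Path,
    *,
    seed: int = 0,
    workers: int = 1,
    alpha_screen: float = 0.05,
    n_perm_screen: int = 1000,
    support_min: int = 20,
    capacity: int = 100_000,
    missing_policy: str = "exclude",
    mode: str = "genotype_pairs",
    scope: str = "lead_set",
    alpha_network: float = 0.05,
    n_perm_network: int = 100_000,
    add_one: bool = False,
    curve_variant: str | None = None,
    curve_grid: list[int] | None = None,
) -> Path:
    """Run screen, scan and network test on a PLINK text dataset.

    Writes ``screen.tsv``, ``pairs.tsv`` (+ metadata side-car),
    ``leads.tsv``, ``summary.tsv``, optionally ``curve.tsv``, and
    ``manifest.json`` into ``out_dir``; returns the output directory.  On a
    stage failure, partial outputs are kept and the manifest records the
    failed stage before the exception propagates.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(seed, 3)
    manifest: dict = {
        "subcommand": "run",
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {
            "ped": {"path": str(ped), "sha256": _sha256(ped)},
            "map": {"path": str(map_file), "sha256": _sha256(map_file)},
        },
        "parameters": {
            "seed": seed,
            "workers": workers,
            "alpha_screen": alpha_screen,
            "n_perm_screen": n_perm_screen,
            "support_min": support_min,
            "capacity": capacity,
            "missing_policy": missing_policy,
            "mode": mode,
            "scope": scope,
            "alpha_network": alpha_network,
            "n_perm_network": n_perm_network,
            "add_one": add_one,
            "curve_variant": curve_variant,
            "curve_grid": curve_grid,
        },
        "stage_seeds": {"screen": seeds[0], "scan": seeds[1], "network": seeds[2]},
        "stages": {},
    }

    def _write_manifest() -> None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
            fh.write("\n")

    stage = "read"
    try:
        t0 = time.monotonic()
        variants = read_map(map_file)
        cohort = read_ped(ped, variants)
        logger.info(
            "read %d individuals (%d cases / %d controls), %d variants",
            cohort.n_individuals,
            cohort.n_cases,
            cohort.n_controls,
            cohort.n_variants,
        )
        manifest["stages"]["read"] = {
            "n_individuals": cohort.n_individuals,
            "n_cases": cohort.n_cases,
            "n_controls": cohort.n_controls,
            "n_variants": cohort.n_variants,
            "seconds": round(time.monotonic() - t0, 3),
        }

        stage = "screen"
        t0 = time.monotonic()
        screen_res = TrendScreen(
            cohort, n_perm=n_perm_screen, alpha=alpha_screen
        ).fit(seed=seeds[0])
        screen_res.to_tsv(out / "screen.tsv")
        logger.info("screen: excluded %d variant(s)", len(screen_res.excluded_ids))
        manifest["stages"]["screen"] = {
            "n_excluded": len(screen_res.excluded_ids),
            "excluded": screen_res.excluded_ids,
            "seconds": round(time.monotonic() - t0, 3),
        }

        stage = "scan"
        t0 = time.monotonic()
        scan_res = DigenicScan(
            cohort,
            support_min=support_min,
            capacity=capacity,
            excluded=screen_res.excluded_ids,
            missing_policy=missing_policy,
        ).fit(workers=workers)
        write_pattern_list(scan_res.ranked, out / "pairs.tsv")
        manifest["stages"]["scan"] = {
            "n_tests": scan_res.ranked.n_tests,
            "n_retained": len(scan_res.ranked),
            "seconds": round(time.monotonic() - t0, 3),
        }

        stage = "network"
        t0 = time.monotonic()
        if len(scan_res.ranked) == 0:
            logger.warning("empty pattern list; skipping network test")
            pd.DataFrame(
                columns=["variant_id", "chrom", "bp", "r", "c", "T",
                         "p_empirical", "gwas_rank"]
            ).to_csv(out / "leads.tsv", sep="\t", index=False)
            manifest["stages"]["network"] = {"n_unique": 0, "n_leads": 0}
        else:
            dnt_res = DigenicNetworkTest(
                scan_res.ranked,
                mode=mode,
                n_perm=n_perm_network,
                alpha=alpha_network,
                add_one=add_one,
            ).fit(seed=seeds[2])
            write_network_outputs(
                dnt_res,
                cohort,
                out,
                scope=scope,
                gwas_ranks=screen_res.gwas_rank_map(),
                seed=seeds[2],
            )
            if curve_variant is not None:
                grid = curve_grid or _default_grid(len(scan_res.ranked))
                curve = connectivity_curve(
                    scan_res.ranked, curve_variant, grid, mode=mode
                )
                pd.DataFrame({"Npatt": curve.grid, "Nc": curve.counts}).to_csv(
                    out / "curve.tsv", sep="\t", index=False
                )
            ns = dnt_res.network_summary(scope=scope)
            manifest["stages"]["network"] = {
                "n_unique": dnt_res.n_unique,
                "n_leads": len(ns.lead_set),
                "S1": ns.S1,
                "S2": ns.S2,
                "R": None if not ns.defined else round(ns.R, 6),
                "seconds": round(time.monotonic() - t0, 3),
            }
        manifest["status"] = "ok"
    except Exception:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        _write_manifest()
        raise
    _write_manifest()
    return out


def _default_grid(n: int) -> list[int]:
    grid = sorted({max(1, (n * k) // 10) for k in range(1, 11)})
    return grid


def write_network_outputs(
    dnt_res,
    cohort: CohortData | None,
    out: Path,
    scope: str,
    gwas_ranks: dict[str, int] | None,
    seed: int,
) -> None:
    """Write leads.tsv (Table-style per-variant rows) and summary.tsv."""
    rows = []
    for s in sorted(dnt_res.stats, key=lambda s: s.r):
        chrom = bp = None
        if cohort is not None:
            try:
                rec = cohort.variants[cohort.variant_index(s.variant_id)]
                chrom, bp = rec.chromosome, rec.position_bp
            except KeyError:
                pass
        rows.append(
            {
                "variant_id": s.variant_id,
                "chrom": chrom,
                "bp": bp,
                "r": s.r,
                "c": s.c,
                "T": s.T,
                "p_empirical": s.p_empirical,
                "gwas_rank": (gwas_ranks or {}).get(s.variant_id),
                "lead": int(s.p_empirical <= dnt_res.model.alpha),
            }
        )
    pd.DataFrame(rows).to_csv(out / "leads.tsv", sep="\t", index=False)
    ns = dnt_res.network_summary(scope=scope)
    pd.DataFrame(
        [
            {
                "n_unique": ns.n_unique,
                "alpha": ns.alpha,
                "scope": ns.scope,
                "mode": ns.mode,
                "S1": ns.S1,
                "S2": ns.S2,
                "R": ns.R,
                "n_perm": dnt_res.null.n_perm,
                "seed": seed,
            }
        ]
    ).to_csv(out / "summary.tsv", sep="\t", index=False)
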