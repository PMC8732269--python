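"""Batch orchestration: manifest-driven quantification and phantom-panel
simulation to disk.

A manifest is a CSV with one analyzed cell per row and columns
``cell_id, image, nucleus_mask, cell_mask, exclusion_mask, group``
(``exclusion_mask`` may be empty).  Per-cell failures are logged with the
failing stage and the run continues; callers inspect the returned failure
list (the CLI turns it into a nonzero exit status).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cpio
from .config import PipelineConfig
from .errors import CellPolarError, StageError, UsageError
from .metrics import quantify_cell
from .synthetic import make_phenotype_panel

__all__ = ["BatchFailure", "run_batch", "simulate_cmd", "MANIFEST_COLUMNS"]

logger = logging.getLogger("cellpolar.batch")

MANIFEST_COLUMNS = ("cell_id", "image", "nucleus_mask", "cell_mask",
                    "exclusion_mask", "group")


@dataclass
class BatchFailure:
    cell_id: str
    stage: str
    reason: str


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise UsageError(f"manifest not found: {path}")
    try:
        df = pd.read_csv(path, dtype=str).fillna("")
    except Exception as exc:
        raise UsageError(f"cannot parse manifest {path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and
               c != "exclusion_mask"]
    if missing:
        raise UsageError(f"manifest lacks columns: {missing}")
    if "exclusion_mask" not in df.columns:
        df["exclusion_mask"] = ""
    return df


def run_batch(manifest: pd.DataFrame | str | Path, config: PipelineConfig,
              base_dir: str | Path | None = None
              ) -> tuple[pd.DataFrame, list[BatchFailure]]:
    """Quantify every cell in a manifest.

    Returns (metrics table, failures).  The table has one row per
    successfully quantified cell with columns cell_id, group,
    mdr_normalized, mdr_raw, asymmetry, mean_angle, domain, config_hash.
    Relative paths in the manifest resolve against ``base_dir`` (defaults
    to the manifest's own directory when a path is given).
    """
    if not isinstance(manifest, pd.DataFrame):
        mpath = Path(manifest)
        if base_dir is None:
            base_dir = mpath.parent
        manifest = read_manifest(mpath)
    base = Path(base_dir) if base_dir is not None else Path(".")

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    rows: list[dict] = []
    failures: list[BatchFailure] = []
    for rec in manifest.to_dict("records"):
        cell_id = str(rec.get("cell_id", "")) or f"row{len(rows) + len(failures)}"
        try:
            image = cpio.read_image(resolve(rec["image"]),
                                    pixel_size=config.pixel_size or 1.0)
            masks = cpio.load_masks(
                resolve(rec["nucleus_mask"]), resolve(rec["cell_mask"]),
                resolve(rec["exclusion_mask"]) if rec.get("exclusion_mask") else None)
            m = quantify_cell(image, masks, config, cell_id=cell_id)
        except StageError as exc:
            logger.warning("cell %s failed at stage %s: %s", cell_id,
                           exc.stage, exc.original)
            failures.append(BatchFailure(cell_id, exc.stage, str(exc.original)))
            continue
        except CellPolarError as exc:
            logger.warning("cell %s failed: %s", cell_id, exc)
            failures.append(BatchFailure(cell_id, "input", str(exc)))
            continue
        rows.append({
            "cell_id": m.cell_id, "group": rec.get("group", ""),
            "mdr_normalized": m.mdr_normalized, "mdr_raw": m.mdr_raw,
            "asymmetry": m.asymmetry, "mean_angle": m.mean_angle,
            "domain": m.domain, "config_hash": config.config_hash,
        })
    table = pd.DataFrame(rows, columns=["cell_id", "group", "mdr_normalized",
                                        "mdr_raw", "asymmetry", "mean_angle",
                                        "domain", "config_hash"])
    return table, failures


def simulate_cmd(phenotype: str, n_cells: int, seed: int,
                 out_dir: str | Path, noise: bool = True) -> Path:
    """Generate a phantom panel and write images, masks, ground truth and
    a batch-ready manifest into ``out_dir``.  Returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = make_phenotype_panel(phenotype, n_cells, seed, noise=noise)
    man_rows, truth_rows = [], []
    for cell in cells:
        stem = cell.cell_id
        cpio.write_image(out / f"{stem}.tif", cell.image)
        cpio.write_mask(out / f"{stem}_nucleus.tif", cell.masks.nucleus)
        cpio.write_mask(out / f"{stem}_cell.tif", cell.masks.cell)
        cpio.write_mask(out / f"{stem}_exclusion.tif", cell.masks.exclusion)
        man_rows.append({
            "cell_id": stem, "image": f"{stem}.tif",
            "nucleus_mask": f"{stem}_nucleus.tif",
            "cell_mask": f"{stem}_cell.tif",
            "exclusion_mask": f"{stem}_exclusion.tif", "group": phenotype,
        })
        truth_rows.append({
            "cell_id": stem, "phenotype": phenotype,
            "mdr_normalized": cell.truth.mdr_normalized,
            "mdr_raw": cell.truth.mdr_raw,
            "asymmetry": cell.truth.asymmetry, "seed": seed,
        })
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False,
                                    float_format="%.6f")
    manifest_path = out / "manifest.csv"
    pd.DataFrame(man_rows).to_csv(manifest_path, index=False)
    return manifest_path
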