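"""End-to-end pipeline: scan -> track -> clean -> aggregate.

Every run writes its outputs plus a reproducibility manifest (config hash,
seed, package versions); the same inputs and config always produce
byte-identical CSVs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .config import PipelineConfig, run_manifest
from .imaging import analyze_slice
from .io import read_node_annotations, read_stack
from .stack import (
    aggregate_internodes,
    clean_profile,
    internodes_to_frame,
    profiles_to_frame,
    track_stems,
)

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger("stemct")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def run_pipeline(
    config: PipelineConfig,
    input_path: str | Path,
    genotype: str = "NA",
    plant_prefix: str = "",
) -> dict[str, Path]:
    """Run the full measurement chain on a slice stack.

    Returns a mapping of artifact names to the files written under the
    configured output directory: the per-slice trait table, the
    per-internode table, and the run manifest.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    try:
        slices = read_stack(input_path)
    except Exception as exc:
        raise PipelineError(f"stage 'scan' failed reading {input_path}: {exc}") from exc
    if not slices:
        raise PipelineError(f"stage 'scan': no slices found under {input_path}")
    logger.info("scan: %d slices from %s", len(slices), input_path)

    slice_traits = [analyze_slice(slc, config.segmentation) for slc in slices]
    profiles = track_stems(
        slice_traits, config.grid, image_shape=slices[0].pixels.shape
    )
    logger.info("track: %d stem profiles", len(profiles))

    node_map: dict[str, list[int]] = {}
    if config.node_annotations is not None:
        node_path = Path(config.node_annotations)
        if not node_path.exists():
            raise PipelineError(
                f"stage 'aggregate': node annotation file not found: {node_path}"
            )
        node_map = read_node_annotations(node_path)

    records = []
    cleaned = []
    for profile in profiles:
        profile.with_nodes(node_map.get(profile.stem_id, []))
        try:
            cp = clean_profile(profile, config.node_half_width, config.outlier_k)
        except Exception as exc:
            raise PipelineError(
                f"stage 'clean' failed for stem {profile.stem_id}: {exc}"
            ) from exc
        cleaned.append(cp)
        records.extend(
            aggregate_internodes(
                cp,
                slice_thickness_mm=slices[0].slice_thickness,
                genotype=genotype,
                plant_id=f"{plant_prefix}{cp.stem_id}",
                node_half_width=config.node_half_width,
            )
        )

    slice_csv = out_dir / "slice_traits.csv"
    internode_csv = out_dir / "internodes.csv"
    manifest_json = out_dir / "manifest.json"
    profiles_to_frame(cleaned).to_csv(slice_csv, index=False, float_format="%.6f")
    internodes_to_frame(records).to_csv(internode_csv, index=False, float_format="%.6f")
    manifest = run_manifest(config, extra={"input": str(input_path)})
    with open(manifest_json, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {
        "slice_traits": slice_csv,
        "internodes": internode_csv,
        "manifest": manifest_json,
    }
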