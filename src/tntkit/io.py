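"""File I/O: multi-page TIFF with pixel-size metadata, CSV tables, sidecars.

Images are written as one TIFF page per channel with the physical pixel
size stored in ImageJ-compatible resolution metadata.  Tabular data (force
traces, lattices, durations, peptide tables) round-trips through headed
CSV.  Ground-truth records live in ``<output>.truth.json`` sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .connectivity import DurationRecord, LatticeState
from .force_trace import ForceTrace
from .pattern_qc import MetadataError, PatternImage
from .proteomics import PeptideTable
from .transfer_assay import TransferTable
from .tube_profile import TubeImage


def write_tiff(path, channels, pixel_size_um: float) -> None:
    """Write channels (2-D arrays) as a multi-page TIFF with pixel size."""
    stack = np.stack([np.asarray(c, dtype=np.float32) for c in channels])
    res = 1.0 / pixel_size_um
    tifffile.imwrite(
        path,
        stack,
        imagej=True,
        resolution=(res, res),
        metadata={"unit": "um", "axes": "CYX"},
    )


def read_tiff(path):
    """Read a multi-page TIFF; returns (list of channels, pixel_size_um)."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        page = tif.pages[0]
        try:
            num, den = page.tags["XResolution"].value
            pixel_size = den / num
        except (KeyError, ZeroDivisionError) as exc:
            raise MetadataError(f"{path}: missing pixel-size metadata") from exc
    if stack.ndim == 2:
        stack = stack[None]
    return [stack[i].astype(float) for i in range(stack.shape[0])], float(pixel_size)


def write_pattern_image(path, image: PatternImage) -> None:
    write_tiff(path, [image.pixels], image.pixel_size_um)


def read_pattern_image(path) -> PatternImage:
    channels, px = read_tiff(path)
    return PatternImage(pixels=channels[0], pixel_size_um=px)


def write_tube_image(path, image: TubeImage) -> None:
    """Two-page TIFF (membrane, actin) + JSON sidecar with axis and masks."""
    write_tiff(path, [image.membrane, image.actin], image.pixel_size_um)
    sidecar = {
        "axis_xy": image.axis_xy.tolist(),
        "cytosol_mask": np.argwhere(image.cytosol_mask).tolist(),
        "background_mask": np.argwhere(image.background_mask).tolist(),
    }
    Path(str(path) + ".regions.json").write_text(json.dumps(sidecar))


def read_tube_image(path) -> TubeImage:
    channels, px = read_tiff(path)
    sidecar = json.loads(Path(str(path) + ".regions.json").read_text())
    shape = channels[0].shape
    cyto = np.zeros(shape, dtype=bool)
    bg = np.zeros(shape, dtype=bool)
    idx = np.asarray(sidecar["cytosol_mask"], dtype=int)
    cyto[idx[:, 0], idx[:, 1]] = True
    idx = np.asarray(sidecar["background_mask"], dtype=int)
    bg[idx[:, 0], idx[:, 1]] = True
    return TubeImage(
        membrane=channels[0],
        actin=channels[1],
        pixel_size_um=px,
        axis_xy=np.asarray(sidecar["axis_xy"], dtype=float),
        cytosol_mask=cyto,
        background_mask=bg,
    )


def write_force_trace(path, trace: ForceTrace) -> None:
    pd.DataFrame({"time_s": trace.time_s, "dx_um": trace.displacement_um}).to_csv(
        path, index=False
    )


def read_force_trace(path, kappa_pn_per_um: float) -> ForceTrace:
    df = pd.read_csv(path)
    return ForceTrace(
        time_s=df["time_s"].to_numpy(),
        displacement_um=df["dx_um"].to_numpy(),
        kappa_pn_per_um=kappa_pn_per_um,
    )


def write_lattice(sites_path, edges_path, lattice: LatticeState) -> None:
    pd.DataFrame(
        [
            {"q": q, "r": r, "occupied": int((q, r) in lattice.occupied)}
            for q, r in lattice.sites
        ]
    ).to_csv(sites_path, index=False)
    rows = []
    for e in sorted(tuple(sorted(e)) for e in lattice.edges):
        (q1, r1), (q2, r2) = e
        rows.append({"q1": q1, "r1": r1, "q2": q2, "r2": r2})
    pd.DataFrame(rows, columns=["q1", "r1", "q2", "r2"]).to_csv(edges_path, index=False)


def read_lattice(sites_path, edges_path) -> LatticeState:
    sites_df = pd.read_csv(sites_path)
    edges_df = pd.read_csv(edges_path)
    sites = [(int(q), int(r)) for q, r in zip(sites_df["q"], sites_df["r"])]
    occupied = {
        (int(q), int(r))
        for q, r, occ in zip(sites_df["q"], sites_df["r"], sites_df["occupied"])
        if occ
    }
    edges = {
        frozenset(((int(a), int(b)), (int(c), int(d))))
        for a, b, c, d in zip(edges_df["q1"], edges_df["r1"], edges_df["q2"], edges_df["r2"])
    }
    return LatticeState(sites=sites, occupied=occupied, edges=edges)


def write_durations(path, records: list[DurationRecord]) -> None:
    pd.DataFrame(
        [{"duration_min": r.duration_min, "censored": int(r.censored)} for r in records]
    ).to_csv(path, index=False)


def read_durations(path) -> list[DurationRecord]:
    df = pd.read_csv(path)
    return [
        DurationRecord(duration_min=float(d), censored=bool(c))
        for d, c in zip(df["duration_min"], df["censored"])
    ]


def write_transfer_table(path, table: TransferTable) -> None:
    pd.DataFrame(
        [
            {
                "condition": table.condition,
                "route": table.route,
                "n_total": table.n_total,
                "n_positive": table.n_positive,
            }
        ]
    ).to_csv(path, index=False)


def read_transfer_table(path) -> TransferTable:
    row = pd.read_csv(path).iloc[0]
    return TransferTable(
        n_total=int(row["n_total"]),
        n_positive=int(row["n_positive"]),
        condition=str(row.get("condition", "")),
        route=str(row.get("route", "coculture")),
    )


def write_peptide_table(path, table: PeptideTable) -> None:
    """CSV with a '# condition:' header comment line mapping samples."""
    mapping = ";".join(f"{s}={c}" for s, c in table.condition_of.items())
    with open(path, "w") as fh:
        fh.write(f"# conditions: {mapping}\n")
        table.df.to_csv(fh, index=False)


def read_peptide_table(path) -> PeptideTable:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# conditions:"):
            raise ValueError("peptide CSV must start with a '# conditions:' line")
        mapping = dict(
            item.split("=") for item in header.split(":", 1)[1].strip().split(";")
        )
        df = pd.read_csv(fh)
    return PeptideTable(df=df, condition_of=mapping)
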