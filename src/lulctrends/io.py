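"""File formats: multi-band TIFF rasters and CSV tables.

Composite cubes are written one TIFF per year with 115 bands in the order
EVI 1..23, red 1..23, NIR 1..23, MIR 1..23, reliability 1..23; partitions
and annual maps are single-band integer TIFFs. Reference samples and all
tabular outputs are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .classes import CATEGORY_ORDER
from .samples import SampleInterpretation
from .scene import (
    BAND_ORDER,
    N_COMPOSITES,
    CompositeCube,
    LandscapePartition,
    SampleRecord,
)

SAMPLE_COLUMNS = ["sample_id", "x", "y", "year", "interpreter"] + [
    f"pct_{c}" for c in CATEGORY_ORDER
]


def write_cube(cube: CompositeCube, out_dir: str | Path) -> list[Path]:
    """One multi-band TIFF per year: 23 composites x 4 bands + 23 flags."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for yi, year in enumerate(cube.years):
        planes = [cube.bands[yi, :, bi].astype(np.float32) for bi in range(len(BAND_ORDER))]
        planes.append(cube.reliability[yi].astype(np.float32))
        stack = np.concatenate(planes, axis=0)          # (115, R, C)
        path = out_dir / f"composites_{year}.tif"
        tifffile.imwrite(path, stack)
        paths.append(path)
    return paths


def read_cube(in_dir: str | Path) -> CompositeCube:
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("composites_*.tif"))
    if not paths:
        raise FileNotFoundError(f"no composites_*.tif under {in_dir}")
    years, bands, rels = [], [], []
    for path in paths:
        years.append(int(path.stem.split("_")[1]))
        stack = tifffile.imread(path)
        nb = len(BAND_ORDER)
        bands.append(stack[: nb * N_COMPOSITES].reshape(nb, N_COMPOSITES, *stack.shape[1:])
                     .transpose(1, 0, 2, 3))
        rels.append(stack[nb * N_COMPOSITES:].astype(np.int8))
    return CompositeCube(
        bands=np.stack(bands).astype(np.float32),
        reliability=np.stack(rels),
        years=tuple(years),
    )


def write_partition(partition: LandscapePartition, out_dir: str | Path) -> tuple[Path, Path]:
    """Single-band integer TIFF of municipality ids plus a municipalities CSV
    carrying the biome/ecoregion assignments and the cell size."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tif = out_dir / "municipalities.tif"
    tifffile.imwrite(tif, partition.municipality_of.astype(np.int32))
    csv = out_dir / "municipalities.csv"
    counts = partition.pixel_counts
    pd.DataFrame.from_records([
        {
            "municipality": int(m),
            "biome": partition.biome_of_municipality[int(m)],
            "ecoregion": partition.ecoregion_of_municipality[int(m)],
            "pixel_count": counts[int(m)],
            "cell_size_m": partition.cell_size_m,
        }
        for m in partition.municipality_ids
    ]).to_csv(csv, index=False)
    return tif, csv


def read_partition(in_dir: str | Path) -> LandscapePartition:
    in_dir = Path(in_dir)
    mun = tifffile.imread(in_dir / "municipalities.tif").astype(np.int32)
    meta = pd.read_csv(in_dir / "municipalities.csv")
    return LandscapePartition(
        rows=mun.shape[0],
        cols=mun.shape[1],
        cell_size_m=float(meta["cell_size_m"].iloc[0]),
        municipality_of=mun,
        biome_of_municipality=dict(zip(meta["municipality"].astype(int),
                                       meta["biome"].astype(int))),
        ecoregion_of_municipality=dict(zip(meta["municipality"].astype(int),
                                           meta["ecoregion"].astype(int))),
    )


def write_samples(records: list[SampleRecord], path: str | Path,
                  cell_size_m: float) -> Path:
    """Two rows (interpreters A and B) per reference footprint."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        for interp, percents, year in (("A", rec.interp_a, rec.year_a),
                                       ("B", rec.interp_b, rec.year_b)):
            row = {
                "sample_id": rec.sample_id,
                "x": rec.col * cell_size_m,
                "y": rec.row * cell_size_m,
                "year": year,
                "interpreter": interp,
            }
            row.update({f"pct_{c}": percents.get(c, 0.0) for c in CATEGORY_ORDER})
            rows.append(row)
    pd.DataFrame(rows, columns=SAMPLE_COLUMNS).to_csv(path, index=False)
    return path


def read_sample_interpretations(path: str | Path) -> list[SampleInterpretation]:
    df = pd.read_csv(path)
    return [
        SampleInterpretation(
            sample_id=int(r["sample_id"]),
            interpreter=str(r["interpreter"]),
            percents={c: float(r[f"pct_{c}"]) for c in CATEGORY_ORDER},
            year=int(r["year"]),
        )
        for _, r in df.iterrows()
    ]


def write_maps(map_stack, out_dir: str | Path) -> list[Path]:
    """Annual five-class maps: one single-band integer TIFF per year."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for yi, year in enumerate(map_stack.years):
        path = out_dir / f"lulc_{year}.tif"
        tifffile.imwrite(path, map_stack.codes[yi].astype(np.uint8))
        paths.append(path)
    map_stack.nodata_fraction.to_csv(out_dir / "nodata_fraction.csv", index=False)
    with open(out_dir / "route_counts.json", "w") as fh:
        json.dump(map_stack.route_counts, fh)
    return paths


def read_maps(in_dir: str | Path):
    from .classifier import AnnualMapStack
    in_dir = Path(in_dir)
    paths = sorted(in_dir.glob("lulc_*.tif"))
    if not paths:
        raise FileNotFoundError(f"no lulc_*.tif under {in_dir}")
    years = tuple(int(p.stem.split("_")[1]) for p in paths)
    codes = np.stack([tifffile.imread(p).astype(np.int8) for p in paths])
    nodata = pd.read_csv(in_dir / "nodata_fraction.csv")
    route_path = in_dir / "route_counts.json"
    route = json.loads(route_path.read_text()) if route_path.exists() else {}
    return AnnualMapStack(codes=codes, years=years, nodata_fraction=nodata,
                         route_counts=route)


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a simple key=value config file (# comments allowed)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, val = line.split("=", 1)
        out[key.strip()] = val.strip()
    return out
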