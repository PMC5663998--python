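"""Readers/writers for the pipeline's plain-text interchange formats.

CSV is the canonical interchange: profile matrices (samples x glycan ids,
percent, with ``diagnosis``/``site`` metadata columns), EIC tables, results
tables.  MS2 peak lists are read/written as two-column text or MGF-style
blocks (negative polarity noted in TITLE).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
from pyteomics import mgf as pyteomics_mgf

from .fragments import Spectrum
from .profiling import GlycanProfile, build_profile

METADATA_COLUMNS = ("diagnosis", "site")


@dataclass
class RunConfig:
    """Validated configuration serialized alongside outputs for provenance."""

    output_dir: str = "results"
    grouping: str = "diagnosis"
    search_tolerance: float = 0.5
    ms2_tolerance: float = 0.3
    seed: int = 0
    n_trees: int = 500
    top_k: int = 4
    cv_folds: int = 5
    profile_path: Optional[str] = None
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.search_tolerance <= 0 or self.ms2_tolerance <= 0:
            raise ValueError("tolerances must be positive")
        if self.grouping not in METADATA_COLUMNS:
            raise ValueError(f"grouping must be one of {METADATA_COLUMNS}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def read_profile_matrix(
    path: str | Path,
    glycan_class: str = "N",
    renormalize: bool = True,
) -> GlycanProfile:
    """Read a combined profile CSV: sample_id, metadata columns, glycan columns.

    Rows that do not sum to 100 (within 0.5) trigger a normalization warning
    and are renormalized when ``renormalize`` is set.  A missing metadata
    column is an error naming the column.
    """
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError("profile CSV must have a 'sample_id' column")
    df = df.set_index("sample_id")
    meta_cols = [c for c in METADATA_COLUMNS if c in df.columns]
    if not meta_cols:
        raise ValueError(
            f"profile CSV is missing a metadata column (need one of {METADATA_COLUMNS})"
        )
    metadata = df[meta_cols]
    values = df.drop(columns=meta_cols)
    bad = values.columns[values.isna().any() | ~values.map(_is_number).all()]
    if len(bad):
        lines = []
        for col in bad:
            mask = values[col].isna() | ~values[col].map(_is_number)
            # +2: header line and 1-based numbering
            lines.extend(int(i) + 2 for i in mask.reset_index(drop=True)[mask.values].index)
        raise ValueError(f"malformed abundance values in columns {list(bad)} (lines {sorted(set(lines))})")
    values = values.astype(float)
    sums = values.sum(axis=1)
    off = (sums - 100.0).abs() > 0.5
    if off.any():
        import warnings

        warnings.warn(
            f"profiles for samples {list(sums.index[off])} do not sum to 100"
            + ("; renormalizing" if renormalize else "")
        )
        if renormalize:
            return build_profile(values, metadata, glycan_class=glycan_class)
    profile = GlycanProfile(abundances=values, metadata=metadata, glycan_class=glycan_class)
    return profile


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def write_profile_matrix(profile: GlycanProfile, path: str | Path) -> None:
    out = pd.concat([profile.metadata, profile.abundances], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path)


def read_eic_table(path: str | Path) -> pd.DataFrame:
    """EIC CSV: glycan_id, mz, charge plus rt_min/area (pre-integrated) or
    rt_min/intensity (raw)."""
    df = pd.read_csv(path)
    if "glycan_id" not in df.columns or "rt_min" not in df.columns:
        raise ValueError("EIC CSV needs 'glycan_id' and 'rt_min' columns")
    if "area" not in df.columns and "intensity" not in df.columns:
        raise ValueError("EIC CSV needs an 'area' or 'intensity' column")
    return df


def write_results_tables(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                         config: Optional[RunConfig] = None) -> list[Path]:
    """Write each results table as CSV; prepend a config-hash comment line."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    tag = f"# config_hash={config.config_hash()}\n" if config is not None else ""
    for name, table in tables.items():
        path = out / f"{name}.csv"
        with open(path, "w") as fh:
            if tag:
                fh.write(tag)
            table.to_csv(fh, index=not isinstance(table.index, pd.RangeIndex))
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

def read_peaklist(path: str | Path, precursor_mz: float, precursor_charge: int,
                  title: str = "") -> Spectrum:
    """Two-column text peak list (m/z, intensity; '#' comments allowed)."""
    peaks = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'mz intensity'")
        peaks.append((float(parts[0]), float(parts[1])))
    return Spectrum(precursor_mz=precursor_mz, precursor_charge=precursor_charge,
                    peaks=peaks, title=title or str(path))


def write_peaklist(spectrum: Spectrum, path: str | Path) -> None:
    lines = [f"# precursor_mz={spectrum.precursor_mz:.4f} charge={spectrum.precursor_charge}-"]
    lines += [f"{mz_:.4f}\t{inten:.4f}" for mz_, inten in spectrum.peaks]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read MGF-style blocks (negative polarity assumed, per TITLE note)."""
    spectra = []
    with pyteomics_mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = entry["params"]
            charge = abs(int(params.get("charge", [1])[0]))
            spectra.append(
                Spectrum(
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=charge,
                    peaks=list(zip(entry["m/z array"], entry["intensity array"])),
                    title=str(params.get("title", "")),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path: str | Path) -> None:
    blocks = []
    for spec in spectra:
        blocks.append(
            {
                "m/z array": [p[0] for p in spec.peaks],
                "intensity array": [p[1] for p in spec.peaks],
                "params": {
                    "title": (spec.title or "spectrum") + " [negative mode]",
                    "pepmass": spec.precursor_mz,
                    "charge": f"{spec.precursor_charge}-",
                },
            }
        )
    pyteomics_mgf.write(blocks, str(path), file_mode="w")
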