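"""Dataset container and delimited-text I/O.

A dataset is a wavelength grid, an intensity matrix (one row per spectrum)
and a manifest table assigning each spectrum its construct label, collection
fiber, rebuild id, exposure and role (``tissue`` or ``standard``). On disk it
is two CSV files: a wide spectra table (``wavelength_nm`` column followed by
one column per spectrum id) and the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .constructs import validate_label
from .spectra import Spectrum, VALID_FIBERS

MANIFEST_COLUMNS = (
    "spectrum_id",
    "construct_label",
    "fiber_id",
    "rebuild_id",
    "exposure_ms",
    "role",
)


@dataclass
class Dataset:
    """In-memory spectra collection: grid, intensity matrix, manifest."""

    wavelengths: np.ndarray
    intensities: np.ndarray  # shape (n_spectra, n_wavelengths)
    manifest: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D matrix")
        if self.intensities.shape != (len(self.manifest), self.wavelengths.size):
            raise ValueError("intensity matrix shape does not match manifest/grid")
        missing = set(MANIFEST_COLUMNS) - set(self.manifest.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.manifest["spectrum_id"].duplicated().any():
            raise ValueError("manifest contains duplicate spectrum ids")

    def __len__(self) -> int:
        return len(self.manifest)

    def get_spectrum(self, key: Union[int, str]) -> Spectrum:
        """Spectrum by integer row position or spectrum id."""
        if isinstance(key, str):
            hits = np.flatnonzero(self.manifest["spectrum_id"].to_numpy() == key)
            if hits.size == 0:
                raise KeyError(f"no spectrum with id {key!r}")
            key = int(hits[0])
        row = self.manifest.iloc[key]
        label = row["construct_label"]
        return Spectrum(
            wavelengths=self.wavelengths,
            intensities=self.intensities[key],
            fiber_id=row["fiber_id"],
            construct_label=None if pd.isna(label) or label == "" else str(label),
            rebuild_id=None if pd.isna(row["rebuild_id"]) else int(row["rebuild_id"]),
            exposure_ms=float(row["exposure_ms"]),
        )

    def select(self, mask: np.ndarray) -> "Dataset":
        """Row subset of the dataset (boolean mask or index array)."""
        manifest = self.manifest.iloc[mask].reset_index(drop=True)
        return Dataset(self.wavelengths, self.intensities[mask], manifest)


def write_dataset(dataset: Dataset, spectra_path, manifest_path) -> None:
    """Write a dataset as the wide spectra CSV plus the manifest CSV."""
    ids = dataset.manifest["spectrum_id"].tolist()
    wide = pd.concat(
        [
            pd.DataFrame({"wavelength_nm": dataset.wavelengths}),
            pd.DataFrame(dataset.intensities.T, columns=ids),
        ],
        axis=1,
    )
    wide.to_csv(spectra_path, index=False, float_format="%.12g")
    dataset.manifest.loc[:, list(MANIFEST_COLUMNS)].to_csv(manifest_path, index=False)


def read_dataset(spectra_path, manifest_path) -> Dataset:
    """Load and validate a spectra CSV + manifest CSV pair.

    Raises ``ValueError`` naming the offending manifest line for missing
    columns, orphan spectrum ids, and malformed construct labels.
    """
    spectra_path, manifest_path = Path(spectra_path), Path(manifest_path)
    wide = pd.read_csv(spectra_path)
    if "wavelength_nm" not in wide.columns:
        raise ValueError(f"{spectra_path}: missing 'wavelength_nm' column")
    manifest = pd.read_csv(
        manifest_path, dtype={"construct_label": "string", "spectrum_id": "string"}
    )
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ValueError(f"{manifest_path}: missing columns {sorted(missing)}")
    manifest["spectrum_id"] = manifest["spectrum_id"].astype(str)
    available = set(wide.columns) - {"wavelength_nm"}
    for line_no, row in enumerate(manifest.itertuples(index=False), start=2):
        if row.spectrum_id not in available:
            raise ValueError(
                f"{manifest_path}:{line_no}: spectrum id {row.spectrum_id!r} "
                f"not present in {spectra_path.name}"
            )
        if row.role not in ("tissue", "standard"):
            raise ValueError(f"{manifest_path}:{line_no}: bad role {row.role!r}")
        if row.role == "tissue":
            try:
                validate_label(str(row.construct_label))
            except ValueError as exc:
                raise ValueError(f"{manifest_path}:{line_no}: {exc}") from exc
        if row.role == "tissue" and row.fiber_id not in VALID_FIBERS:
            raise ValueError(f"{manifest_path}:{line_no}: bad fiber_id {row.fiber_id!r}")
    manifest["construct_label"] = manifest["construct_label"].astype(object).where(
        manifest["construct_label"].notna(), None
    )
    intensities = wide[manifest["spectrum_id"].tolist()].to_numpy(dtype=float).T
    return Dataset(
        wavelengths=wide["wavelength_nm"].to_numpy(dtype=float),
        intensities=intensities,
        manifest=manifest.reset_index(drop=True),
    )


def load_deposited_repository(path) -> Dataset:
    """Extension point for the publicly deposited measured-spectra archive.

    The archive's internal layout is not documented alongside the data; once
    it is known, this loader should translate it into the spectra + manifest
    layout of :func:`read_dataset`. Until then the function only raises.
    """
    raise NotImplementedError(
        "the layout of the deposited archive is undocumented; arrange the "
        "data as a spectra CSV + manifest CSV and use read_dataset instead"
    )
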