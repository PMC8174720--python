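"""Genotype calls relative to a reference variety, and barcode rendering.

Each accession's amplicon pattern at each panel marker is coded against the
reference variety: ``a`` = same product size as the reference, ``b`` =
different (the insertion/deletion allele), ``h`` = heterozygous (both
bands), ``-`` = missing/failed. Profiles render as binary barcodes — white
for ``a``, black for ``b`` — either as a 1D strip or a 2D block grid, and
decode losslessly back to the profile.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .variants import Zygosity

__all__ = [
    "CALL_SYMBOLS",
    "GenotypeProfile",
    "GenotypeMatrix",
    "BarcodeImage",
    "BarcodeError",
    "call_from_zygosity",
    "encode_barcode",
    "decode_barcode",
    "homology",
    "homology_counts",
]

#: closed symbol alphabet: reference-like, variant, heterozygous, missing
CALL_SYMBOLS = ("a", "b", "h", "-")

_ZYGOSITY_TO_CALL = {
    Zygosity.HOM_REF: "a",
    Zygosity.HOM_ALT: "b",
    Zygosity.HET: "h",
    Zygosity.MISSING: "-",
}

# cell codes inside a BarcodeImage grid
CELL_A, CELL_B, CELL_H, CELL_MISSING, CELL_PAD = 0, 1, 2, 3, 4
_CALL_TO_CELL = {"a": CELL_A, "b": CELL_B, "h": CELL_H, "-": CELL_MISSING}
_CELL_TO_CALL = {v: k for k, v in _CALL_TO_CELL.items()}

# grayscale rendering: white=a, black=b; lenient mode half-tones h and
# light-hatches missing
_CELL_GRAY = {CELL_A: 255, CELL_B: 0, CELL_H: 127, CELL_MISSING: 220, CELL_PAD: 255}
_CELL_SVG_FILL = {
    CELL_A: "#ffffff",
    CELL_B: "#000000",
    CELL_H: "#7f7f7f",
    CELL_MISSING: "#dcdcdc",
    CELL_PAD: "#ffffff",
}


class BarcodeError(ValueError):
    """Raised on profile/barcode contract violations."""


def call_from_zygosity(z: Zygosity) -> str:
    """Map a zygosity class to its banding-pattern symbol (a/b/h/-)."""
    return _ZYGOSITY_TO_CALL[z]


@dataclass(frozen=True)
class GenotypeProfile:
    """Ordered a/b/h/- calls of one accession over the panel markers."""

    accession_id: str
    calls: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = [c for c in self.calls if c not in CALL_SYMBOLS]
        if bad:
            raise BarcodeError(
                f"{self.accession_id}: invalid call symbol(s) {sorted(set(bad))}"
            )
        object.__setattr__(self, "calls", tuple(self.calls))

    def __len__(self) -> int:
        return len(self.calls)

    def differences(self, other: "GenotypeProfile") -> int:
        """Number of markers with unequal calls (both non-missing)."""
        return sum(
            1
            for x, y in zip(self.calls, other.calls)
            if x != "-" and y != "-" and x != y
        )


@dataclass
class GenotypeMatrix:
    """Rectangular accession x marker matrix of a/b/h/- calls.

    The reference variety, if included, is all-``a`` by construction — it is
    identical to itself at every marker.
    """

    marker_ids: list[str]
    profiles: list[GenotypeProfile]
    reference_id: str | None = None

    def __post_init__(self) -> None:
        n = len(self.marker_ids)
        for p in self.profiles:
            if len(p) != n:
                raise BarcodeError(
                    f"profile {p.accession_id} has {len(p)} calls for {n} markers"
                )
        ids = [p.accession_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            raise BarcodeError("duplicate accession ids in matrix")
        if self.reference_id is not None and self.reference_id in ids:
            ref = self.profile(self.reference_id)
            if any(c != "a" for c in ref.calls):
                raise BarcodeError(
                    f"reference profile {self.reference_id} contains non-'a' calls"
                )

    @property
    def accession_ids(self) -> list[str]:
        return [p.accession_id for p in self.profiles]

    def profile(self, accession_id: str) -> GenotypeProfile:
        for p in self.profiles:
            if p.accession_id == accession_id:
                return p
        raise KeyError(accession_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [list(p.calls) for p in self.profiles],
            index=self.accession_ids,
            columns=self.marker_ids,
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, reference_id: str | None = None
    ) -> "GenotypeMatrix":
        profiles = [
            GenotypeProfile(str(idx), tuple(str(c) for c in row))
            for idx, row in zip(df.index, df.to_numpy())
        ]
        return cls(list(map(str, df.columns)), profiles, reference_id)

    @classmethod
    def read_csv(
        cls, path: str | Path, reference_id: str | None = None, sep: str | None = None
    ) -> "GenotypeMatrix":
        """Read an accession x marker call matrix (CSV or TSV, rows = accessions)."""
        if sep is None:
            sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
        return cls.from_dataframe(df, reference_id)

    def write_csv(self, path: str | Path, sep: str = ",") -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, sep=sep)
        return path


@dataclass
class BarcodeImage:
    """Binary cell grid for one profile plus the metadata needed to decode it.

    ``cells`` holds integer cell codes row-major in panel order; cells past
    the panel size are padding. A one-cell quiet border is added only at
    render time and never enters the grid.
    """

    layout: str  # "1D" | "2D"
    rows: int
    cols: int
    cells: np.ndarray
    marker_ids: list[str]
    accession_id: str = ""

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.layout not in ("1D", "2D"):
            raise BarcodeError(f"unknown layout {self.layout!r}")
        if self.cells.shape != (self.rows, self.cols):
            raise BarcodeError("cell grid shape disagrees with rows/cols")
        if self.rows * self.cols < len(self.marker_ids):
            raise BarcodeError(
                f"{self.rows}x{self.cols} grid cannot hold {len(self.marker_ids)} markers"
            )

    # --- serialization -------------------------------------------------

    def to_text(self) -> str:
        """Calls as a plain string over a/b (h/- in lenient images)."""
        flat = self.cells.ravel()[: len(self.marker_ids)]
        return "".join(_CELL_TO_CALL[int(c)] for c in flat)

    def to_svg(self, cell_px: int = 10, border_cells: int = 1) -> str:
        """Deterministic SVG: one rect per cell plus a white quiet border."""
        w = (self.cols + 2 * border_cells) * cell_px
        h = (self.rows + 2 * border_cells) * cell_px
        parts = [
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{w}" height="{h}" '
            f'viewBox="0 0 {w} {h}">',
            f'<rect width="{w}" height="{h}" fill="#ffffff"/>',
        ]
        for r in range(self.rows):
            for c in range(self.cols):
                fill = _CELL_SVG_FILL[int(self.cells[r, c])]
                if fill == "#ffffff":
                    continue
                x = (c + border_cells) * cell_px
                y = (r + border_cells) * cell_px
                parts.append(
                    f'<rect x="{x}" y="{y}" width="{cell_px}" height="{cell_px}" fill="{fill}"/>'
                )
        parts.append("</svg>")
        return "\n".join(parts)

    def to_png(self, path: str | Path, cell_px: int = 10, border_cells: int = 1) -> Path:
        grid = np.full(
            (self.rows + 2 * border_cells, self.cols + 2 * border_cells),
            255,
            dtype=np.uint8,
        )
        for r in range(self.rows):
            for c in range(self.cols):
                grid[r + border_cells, c + border_cells] = _CELL_GRAY[int(self.cells[r, c])]
        img = Image.fromarray(grid, mode="L").resize(
            (grid.shape[1] * cell_px, grid.shape[0] * cell_px), Image.NEAREST
        )
        path = Path(path)
        img.save(path)
        return path

    def metadata(self) -> dict:
        """JSON-serializable sidecar describing the layout for decoding."""
        return {
            "layout": self.layout,
            "rows": self.rows,
            "cols": self.cols,
            "order": "row-major",
            "marker_ids": list(self.marker_ids),
            "accession_id": self.accession_id,
            "cell_codes": {"a": CELL_A, "b": CELL_B, "h": CELL_H, "-": CELL_MISSING, "pad": CELL_PAD},
        }

    def write_sidecar(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.metadata(), indent=1) + "\n")
        return path


def encode_barcode(
    profile: GenotypeProfile,
    marker_ids: Sequence[str],
    layout: str = "2D",
    rows: int | None = None,
    cols: int | None = None,
    strict: bool = True,
) -> BarcodeImage:
    """Render a profile as a barcode grid.

    1D uses a single row of one module per marker. 2D defaults to 5 rows
    (a 50-marker panel becomes the compact 5x10 block), filled row-major in
    panel order; cells beyond the panel are padding. Under the default
    strict policy, heterozygous or missing calls are an error — the binary
    barcode has no cell for them; lenient mode renders them as half-tone /
    light cells which the decoder maps back to h and -.
    """
    n = len(profile)
    if n != len(marker_ids):
        raise BarcodeError(
            f"profile has {n} calls but panel lists {len(marker_ids)} markers"
        )
    if strict:
        offending = [
            m for m, c in zip(marker_ids, profile.calls) if c in ("h", "-")
        ]
        if offending:
            raise BarcodeError(
                f"{profile.accession_id}: non-binary calls at {', '.join(offending)} "
                "(use strict=False to render them)"
            )
    if layout == "1D":
        rows, cols = 1, n
    elif layout == "2D":
        if rows is None:
            rows = 5 if n >= 5 else 1
        if cols is None:
            cols = math.ceil(n / rows)
    else:
        raise BarcodeError(f"unknown layout {layout!r}")
    if rows * cols < n:
        raise BarcodeError(f"{rows}x{cols} grid too small for {n} markers")
    flat = np.full(rows * cols, CELL_PAD, dtype=np.int8)
    flat[:n] = [_CALL_TO_CELL[c] for c in profile.calls]
    return BarcodeImage(
        layout=layout,
        rows=rows,
        cols=cols,
        cells=flat.reshape(rows, cols),
        marker_ids=list(marker_ids),
        accession_id=profile.accession_id,
    )


def decode_barcode(img: BarcodeImage) -> GenotypeProfile:
    """Exact inverse of :func:`encode_barcode`; padding cells are ignored."""
    n = len(img.marker_ids)
    flat = img.cells.ravel()
    if flat.size < n:
        raise BarcodeError(
            f"grid has {flat.size} cells but panel declares {n} markers"
        )
    if any(int(c) == CELL_PAD for c in flat[:n]):
        raise BarcodeError("padding cell inside the declared panel area")
    calls = tuple(_CELL_TO_CALL[int(c)] for c in flat[:n])
    return GenotypeProfile(img.accession_id, calls)


def matrix_from_variants(
    marker_sites: Sequence[tuple[str, object]],
    accessions: Sequence[str],
    reference_id: str | None = None,
) -> GenotypeMatrix:
    """Build a call matrix from (marker_id, InDelVariant) pairs in panel order."""
    marker_ids = [mid for mid, _ in marker_sites]
    profiles = []
    for a in accessions:
        calls = tuple(
            call_from_zygosity(v.genotypes.get(a, Zygosity.MISSING))
            for _, v in marker_sites
        )
        profiles.append(GenotypeProfile(a, calls))
    return GenotypeMatrix(marker_ids, profiles, reference_id)


def homology_counts(
    p1: GenotypeProfile,
    p2: GenotypeProfile,
    missing_policy: str = "exclude",
) -> tuple[int, int]:
    """(matching markers, compared markers) between two profiles.

    Under ``missing_policy='exclude'`` (default) any marker where either
    call is '-' drops out of both counts; ``'strict'`` raises instead.
    Heterozygous calls match only heterozygous calls.
    """
    if len(p1) != len(p2):
        raise BarcodeError(
            f"profiles {p1.accession_id}/{p2.accession_id} have different panel sizes"
        )
    if missing_policy not in ("exclude", "strict"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    matches = compared = 0
    for x, y in zip(p1.calls, p2.calls):
        if x == "-" or y == "-":
            if missing_policy == "strict":
                raise BarcodeError(
                    f"missing call while comparing {p1.accession_id} and {p2.accession_id}"
                )
            continue
        compared += 1
        if x == y:
            matches += 1
    return matches, compared


def homology(
    p1: GenotypeProfile,
    p2: GenotypeProfile,
    missing_policy: str = "exclude",
) -> float:
    """Fraction of compared markers with identical calls (simple matching)."""
    matches, compared = homology_counts(p1, p2, missing_policy)
    if compared == 0:
        raise BarcodeError(
            f"no comparable markers between {p1.accession_id} and {p2.accession_id}"
        )
    return matches / compared
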