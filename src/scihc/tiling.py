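"""Fixed-size chunking and multiresolution pyramids.

Large whole-slide rasters are processed as a grid of 512x512 px tiles
(edge tiles keep their true, smaller size so that reassembling level-0
tiles reproduces the source bit-exactly) plus a mean-pooled pyramid for
coarse operations such as global rigid alignment.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

DEFAULT_TILE_SIZE = 512


@dataclass(frozen=True)
class TileGrid:
    width: int
    height: int
    tile_size: int = DEFAULT_TILE_SIZE

    @property
    def n_cols(self) -> int:
        return -(-self.width // self.tile_size)

    @property
    def n_rows(self) -> int:
        return -(-self.height // self.tile_size)

    @property
    def n_tiles(self) -> int:
        return self.n_cols * self.n_rows

    def tile_bounds(self, row: int, col: int) -> tuple[int, int, int, int]:
        """(x0, y0, x1, y1) half-open pixel bounds of a level-0 tile."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"tile ({row}, {col}) outside grid")
        x0 = col * self.tile_size
        y0 = row * self.tile_size
        return x0, y0, min(x0 + self.tile_size, self.width), min(
            y0 + self.tile_size, self.height
        )

    def tile_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0, x1, y1 = self.tile_bounds(row, col)
        return (x0 + x1 - 1) / 2.0, (y0 + y1 - 1) / 2.0

    def iter_tiles(self):
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield row, col, self.tile_bounds(row, col)

    def extract(self, image: np.ndarray, row: int, col: int) -> np.ndarray:
        x0, y0, x1, y1 = self.tile_bounds(row, col)
        return image[y0:y1, x0:x1]

    def tile_path(self, level: int, row: int, col: int) -> str:
        return os.path.join("tiles", f"L{level}", f"{row}_{col}.png")


def build_tile_grid(width: int, height: int, tile_size: int = DEFAULT_TILE_SIZE) -> TileGrid:
    if width <= 0 or height <= 0 or tile_size <= 0:
        raise ValueError("width, height and tile_size must all be > 0")
    return TileGrid(width=width, height=height, tile_size=tile_size)


def assemble(grid: TileGrid, tiles: dict[tuple[int, int], np.ndarray]) -> np.ndarray:
    """Reassemble level-0 tiles into the full raster (lossless)."""
    sample = next(iter(tiles.values()))
    shape = (grid.height, grid.width) + sample.shape[2:]
    out = np.zeros(shape, dtype=sample.dtype)
    for (row, col), tile in tiles.items():
        x0, y0, x1, y1 = grid.tile_bounds(row, col)
        out[y0:y1, x0:x1] = tile
    return out


def downsample2x(image: np.ndarray) -> np.ndarray:
    """2x2 mean pooling; odd trailing rows/cols are averaged over the
    pixels actually present, so level k has dimensions ceil(dim / 2^k)."""
    img = np.asarray(image, dtype=np.float64)
    h, w = img.shape[:2]
    oh, ow = -(-h // 2), -(-w // 2)
    out = np.zeros((oh, ow) + img.shape[2:])
    cnt = np.zeros((oh, ow) + (1,) * (img.ndim - 2))
    for dy in (0, 1):
        for dx in (0, 1):
            block = img[dy::2, dx::2]
            out[: block.shape[0], : block.shape[1]] += block
            cnt[: block.shape[0], : block.shape[1]] += 1
    out /= cnt
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return np.clip(np.rint(out), info.min, info.max).astype(image.dtype)
    return out.astype(image.dtype)


def build_pyramid(image: np.ndarray, levels: int) -> list[np.ndarray]:
    """Mean-pooled pyramid; level 0 is the input unchanged."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    pyramid = [np.asarray(image)]
    for _ in range(1, levels):
        pyramid.append(downsample2x(pyramid[-1]))
    return pyramid
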