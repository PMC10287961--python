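"""Tiled, worker-count-independent evaluation of matrix kernels.

The output matrix is partitioned into rectangular tiles; a pure kernel
computes each tile from its (row range, column range).  Because every
tile is an independent pure function of its index ranges, the assembled
result is identical for any tile size and any number of workers.
Workers are threads: the numpy kernels used here release the GIL.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor

import numpy as np

__all__ = ["TileError", "parallel_map_tiles"]

logger = logging.getLogger(__name__)


class TileError(RuntimeError):
    """A kernel failure, annotated with the tile coordinates."""

    def __init__(self, tile: tuple[int, int], cause: BaseException):
        self.tile = tile
        self.cause = cause
        super().__init__(f"kernel failed on tile {tile}: {cause!r}")


def parallel_map_tiles(
    shape: tuple[int, int],
    tile_size: int,
    n_workers: int,
    kernel,
) -> np.ndarray:
    """Assemble ``out[rows, cols] = kernel(rows, cols)`` tile by tile.

    ``kernel(row_slice, col_slice)`` must be a pure function returning
    the dense block for that tile.  Exceptions are re-raised as
    :class:`TileError` naming the (row-tile, col-tile) coordinates.
    """
    n_rows, n_cols = shape
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    out = np.empty(shape, dtype=float)
    tiles = [
        ((ti, tj), slice(i, min(i + tile_size, n_rows)), slice(j, min(j + tile_size, n_cols)))
        for ti, i in enumerate(range(0, n_rows, tile_size))
        for tj, j in enumerate(range(0, n_cols, tile_size))
    ]

    def run(tile):
        coords, rs, cs = tile
        try:
            block = kernel(rs, cs)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise TileError(coords, exc) from exc
        out[rs, cs] = block

    if n_workers <= 1:
        for tile in tiles:
            run(tile)
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            for future in [pool.submit(run, t) for t in tiles]:
                future.result()
    logger.debug("assembled %d tiles for shape %s", len(tiles), shape)
    return out
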