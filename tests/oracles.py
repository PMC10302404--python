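"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — per-cell walks, flood fills,
recursive subtree sums — and shares no code with the package beyond the
documented D8 code table, so agreement is meaningful.
"""

from __future__ import annotations

import numpy as np

# the documented D8 code table (E, SE, S, SW, W, NW, N, NE)
STEP = {
    1: (0, 1), 2: (1, 1), 4: (1, 0), 8: (1, -1),
    16: (0, -1), 32: (-1, -1), 64: (-1, 0), 128: (-1, 1),
}


def step_once(fdr_values: np.ndarray, cell: tuple[int, int]):
    """One downstream step by table lookup; None when it leaves the domain."""
    code = int(fdr_values[cell])
    if code not in STEP:
        return None
    drow, dcol = STEP[code]
    nxt = (cell[0] + drow, cell[1] + dcol)
    n_rows, n_cols = fdr_values.shape
    if not (0 <= nxt[0] < n_rows and 0 <= nxt[1] < n_cols):
        return None
    return nxt


def accumulation_by_reachability(fdr_values: np.ndarray) -> np.ndarray:
    """acc(c) = number of cells whose downstream walk passes through c
    (self included); sink cells (no valid code) trap the walk."""
    n_rows, n_cols = fdr_values.shape
    acc = np.zeros((n_rows, n_cols), dtype=int)
    for row in range(n_rows):
        for col in range(n_cols):
            cell = (row, col)
            seen = set()
            while cell is not None and cell not in seen:
                acc[cell] += 1
                seen.add(cell)
                cell = step_once(fdr_values, cell)
    return acc


def flood_fill_labels(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Breadth-first flood-fill labelling, 1-based, row-major discovery."""
    offsets = (
        [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
        if connectivity == 8
        else [(-1, 0), (0, -1), (0, 1), (1, 0)]
    )
    n_rows, n_cols = mask.shape
    labels = np.zeros((n_rows, n_cols), dtype=int)
    current = 0
    for row in range(n_rows):
        for col in range(n_cols):
            if mask[row, col] and labels[row, col] == 0:
                current += 1
                frontier = [(row, col)]
                labels[row, col] = current
                while frontier:
                    r0, c0 = frontier.pop()
                    for dr, dc in offsets:
                        rr, cc = r0 + dr, c0 + dc
                        if (
                            0 <= rr < n_rows and 0 <= cc < n_cols
                            and mask[rr, cc] and labels[rr, cc] == 0
                        ):
                            labels[rr, cc] = current
                            frontier.append((rr, cc))
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two labelings induce the same partition (up to renumbering)."""
    if a.shape != b.shape or ((a > 0) != (b > 0)).any():
        return False
    mapping: dict[int, int] = {}
    back: dict[int, int] = {}
    for x, y in zip(a.ravel(), b.ravel()):
        if x == 0:
            continue
        if mapping.setdefault(int(x), int(y)) != y:
            return False
        if back.setdefault(int(y), int(x)) != x:
            return False
    return True


def walk_to_stream(fdr_values: np.ndarray, stream: np.ndarray, start, max_steps):
    """Step-by-step flowpath oracle; returns (cells, terminal_name)."""
    cells = [start]
    if stream[start]:
        return cells, "reached_stream"
    seen = {start}
    current = start
    for _ in range(max_steps):
        code = int(fdr_values[current])
        nxt = step_once(fdr_values, current)
        if nxt is None:
            return cells, ("hit_nodata" if code not in STEP else "exited_grid")
        if stream[nxt]:
            return cells, "reached_stream"
        if nxt in seen:
            return cells, "loop_detected"
        cells.append(nxt)
        seen.add(nxt)
        current = nxt
    return cells, "max_steps"


def group_pixels(patch_labels: np.ndarray, catchments: np.ndarray, cat_nodata):
    """Per-pixel (patch, catchment) grouping; catchment None when nodata."""
    groups: dict[tuple[int, object], set] = {}
    n_rows, n_cols = patch_labels.shape
    for row in range(n_rows):
        for col in range(n_cols):
            patch = int(patch_labels[row, col])
            if patch == 0:
                continue
            cat = catchments[row, col]
            key = (patch, None if cat == cat_nodata else int(cat))
            groups.setdefault(key, set()).add((row, col))
    return groups


def subtree_sums(children: dict, local: dict, node):
    """Recursive watershed sum: node value plus all upstream values."""
    return local[node] + sum(
        subtree_sums(children, local, child) for child in children.get(node, [])
    )


def random_acyclic_fdr(rng: np.random.Generator, shape, p_nodata=0.1) -> np.ndarray:
    """A random valid acyclic D8 grid: steepest descent on a random
    permutation surface (strictly decreasing elevation => acyclic), with
    some cells knocked out to nodata (0)."""
    n_rows, n_cols = shape
    z = rng.permutation(n_rows * n_cols).reshape(shape).astype(float)
    fdr = np.zeros(shape, dtype=int)
    for row in range(n_rows):
        for col in range(n_cols):
            best_code, best_drop = 0, 0.0
            for code, (dr, dc) in STEP.items():
                rr, cc = row + dr, col + dc
                if 0 <= rr < n_rows and 0 <= cc < n_cols:
                    dist = np.sqrt(2.0) if dr and dc else 1.0
                    drop = (z[row, col] - z[rr, cc]) / dist
                    if drop > best_drop:
                        best_code, best_drop = code, drop
            fdr[row, col] = best_code
    knockout = rng.random(shape) < p_nodata
    fdr[knockout] = 0
    return fdr
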