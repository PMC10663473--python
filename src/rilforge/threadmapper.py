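"""Principal-component marker ordering ("Threadmapper"-style).

Markers of one linkage group, encoded +1/-1/0 across the RILs, lie close to
a one-dimensional curve in the principal-component space of the markers-by-
lines matrix; the order of markers along that curve is the map order, and
the orthogonal distance of a marker from the curve falls as its data
quality rises.  Running the decomposition on the markers-by-lines matrix
(rather than on a markers-by-markers distance matrix) keeps the input small
and the computation fast.

The ordering device used here is deterministic seriation: a minimum
spanning tree over map-expansion-corrected pairwise distances, whose
diameter path is the backbone order; off-path markers are inserted next to
their nearest backbone neighbor on the side that adds the least path
length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree, shortest_path

from .genotype_core import GenotypeMatrix, MarkerInfo, SignedMatrix, encode_signed
from .mapdist import PairwiseR, haldane_cM, haldane_waddington_r, pairwise_R

__all__ = [
    "Projection",
    "OrderingResult",
    "ThreadmapResult",
    "project",
    "cluster_linkage_groups",
    "order_along_curve",
    "export_3d",
    "threadmap",
]

_UNLINKED_CM = 300.0  # stand-in distance for pairs with R >= 0.5
_UNDEFINED = 1e7  # pairs with too few informative lines


@dataclass
class Projection:
    """Principal-component scores of the markers (markers x k)."""

    markers: list[str]
    coords: np.ndarray
    explained_variance: np.ndarray

    def coords_of(self, marker_ids: Sequence[str]) -> np.ndarray:
        pos = {m: i for i, m in enumerate(self.markers)}
        return self.coords[[pos[m] for m in marker_ids]]


@dataclass
class OrderingResult:
    """One linkage group's marker order and per-marker off-curve distance."""

    order: list[str]
    off_curve_distance: dict[str, float]


@dataclass
class ThreadmapResult:
    projection: Projection
    groups: pd.Series  # marker -> LG label, largest group first
    orders: dict[str, OrderingResult]
    pairwise: PairwiseR


def project(s: SignedMatrix | GenotypeMatrix, k: int = 3) -> Projection:
    """Project markers into the first ``k`` principal components.

    Markers are the observations and lines the variables; each line
    (column) is centered to mean zero, no scaling (the +-1 encoding is
    already on a common scale).  Component signs are fixed so the score of
    largest magnitude on each component is positive, making repeated runs
    bit-identical.
    """
    if isinstance(s, GenotypeMatrix):
        s = encode_signed(s)
    if k < 2:
        raise ValueError("k must be >= 2")
    X = s.values.astype(np.float64)
    if X.shape[0] < k or X.shape[1] < k:
        raise ValueError(f"need at least k={k} markers and lines")
    X = X - X.mean(axis=0, keepdims=True)
    U, sv, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((sv > sv[0] * 1e-12).sum()) if sv.size and sv[0] > 0 else 0
    if k > rank:
        raise ValueError(f"k={k} exceeds matrix rank {rank}")
    coords = U[:, :k] * sv[:k]
    for j in range(k):
        i_star = int(np.argmax(np.abs(coords[:, j])))
        if coords[i_star, j] < 0:
            coords[:, j] = -coords[:, j]
    denom = max(X.shape[0] - 1, 1)
    return Projection(list(s.markers), coords, sv[:k] ** 2 / denom)


def cluster_linkage_groups(pr: PairwiseR, link_threshold: float = 0.2) -> pd.Series:
    """Assign markers to linkage groups by single linkage.

    Two markers join when their R (uncorrected) is below the threshold and
    the pair is reliably scored; linkage groups are the connected
    components, labeled LG1, LG2, ... from the largest down (ties broken by
    first marker id).
    """
    if not 0.0 < link_threshold < 0.5:
        raise ValueError("link_threshold must be in (0, 0.5)")
    adj = pr.reliable & (np.nan_to_num(pr.R, nan=1.0) < link_threshold)
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    comps: list[list[int]] = [[] for _ in range(n_comp)]
    for i, c in enumerate(labels):
        comps[c].append(i)
    comps.sort(key=lambda idx: (-len(idx), pr.markers[idx[0]]))
    out = pd.Series(index=pr.markers, dtype=object)
    for rank, idx in enumerate(comps, start=1):
        for i in idx:
            out.iloc[i] = f"LG{rank}"
    return out


def _seriation_distances(pr: PairwiseR, coords: np.ndarray) -> np.ndarray:
    """Map-expansion-corrected cM distances with a geometric tie-breaker."""
    R = pr.R.copy()
    D = np.full(R.shape, _UNLINKED_CM)
    ok = pr.reliable & np.isfinite(R) & (R < 0.5)
    D[ok] = haldane_cM(haldane_waddington_r(R[ok]))
    D[~pr.reliable] = _UNDEFINED
    # Euclidean coordinate distance breaks ties among equal cM distances
    diff = coords[:, None, :] - coords[None, :, :]
    euclid = np.sqrt((diff**2).sum(axis=-1))
    scale = euclid.max() or 1.0
    D = D + 1e-6 * euclid / scale
    np.fill_diagonal(D, 0.0)
    return D


def _diameter_path(tree: csr_matrix, n: int) -> list[int]:
    """Longest weighted path of a spanning tree by double sweep."""
    sym = tree + tree.T
    d0 = shortest_path(sym, directed=False, indices=0)
    u = int(np.argmax(np.where(np.isfinite(d0), d0, -1)))
    du, pred = shortest_path(sym, directed=False, indices=u, return_predecessors=True)
    v = int(np.argmax(np.where(np.isfinite(du), du, -1)))
    path = [v]
    while path[-1] != u:
        p = pred[path[-1]]
        if p < 0:
            break
        path.append(int(p))
    return path[::-1]


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return float(np.linalg.norm(p - a))
    t = np.clip(float((p - a) @ ab) / denom, 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def order_along_curve(
    lg_markers: Sequence[str],
    proj: Projection,
    pr: PairwiseR,
    info: Sequence[MarkerInfo] | None = None,
) -> OrderingResult:
    """Order one linkage group's markers along the embedded curve.

    The backbone is the diameter path of a minimum spanning tree over
    corrected pairwise distances; remaining markers are inserted adjacent
    to their nearest backbone neighbor on the side that adds the least path
    length.  Orientation is fixed by correlation with physical positions
    when annotation is supplied, otherwise so that the first marker id is
    lexicographically no greater than the last.
    """
    markers = list(lg_markers)
    if len(markers) < 2:
        raise ValueError("a linkage group needs at least 2 markers to order")
    sub = pr.submatrix(markers)
    coords = proj.coords_of(markers)
    D = _seriation_distances(sub, coords)

    finite = D < _UNDEFINED / 2
    np.fill_diagonal(finite, True)
    n_comp, labels = connected_components(csr_matrix(finite), directed=False)
    if n_comp > 1:
        parts = [
            [markers[i] for i in np.nonzero(labels == c)[0]][:5] for c in range(n_comp)
        ]
        raise ValueError(f"linkage group is disconnected; components start with {parts}")

    mst = minimum_spanning_tree(csr_matrix(D + 1e-9))
    backbone = _diameter_path(mst, len(markers))
    order = list(backbone)
    remaining = [i for i in range(len(markers)) if i not in set(backbone)]
    # nearest-first insertion keeps placement deterministic and local
    remaining.sort(key=lambda i: (D[i, backbone].min(), markers[i]))
    for m in remaining:
        pos = {node: k for k, node in enumerate(order)}
        nearest = min(order, key=lambda node: (D[m, node], markers[node]))
        k = pos[nearest]
        candidates = []  # (added_length, insertion_index)
        if k == 0:
            candidates.append((D[m, order[0]], 0))
        else:
            a, b = order[k - 1], order[k]
            candidates.append((D[a, m] + D[m, b] - D[a, b], k))
        if k == len(order) - 1:
            candidates.append((D[m, order[-1]], len(order)))
        else:
            a, b = order[k], order[k + 1]
            candidates.append((D[a, m] + D[m, b] - D[a, b], k + 1))
        _, where = min(candidates)
        order.insert(where, m)

    ordered_ids = [markers[i] for i in order]
    ordered_ids = _orient(ordered_ids, info)
    idx = {m: i for i, m in enumerate(markers)}
    off: dict[str, float] = {}
    for j, mid in enumerate(ordered_ids):
        if j == 0 or j == len(ordered_ids) - 1:
            off[mid] = 0.0
        else:
            p = coords[idx[mid]]
            a = coords[idx[ordered_ids[j - 1]]]
            b = coords[idx[ordered_ids[j + 1]]]
            off[mid] = _point_segment_distance(p, a, b)
    return OrderingResult(order=ordered_ids, off_curve_distance=off)


def _orient(order: list[str], info: Sequence[MarkerInfo] | None) -> list[str]:
    if info:
        bp = {m.marker_id: m.position_bp for m in info}
        ranks = [(i, bp[m]) for i, m in enumerate(order) if m in bp]
        if len(ranks) >= 2:
            i_arr = np.array([r[0] for r in ranks], dtype=float)
            b_arr = np.array([r[1] for r in ranks], dtype=float)
            corr = np.corrcoef(i_arr, b_arr)[0, 1]
            if np.isfinite(corr) and corr < 0:
                return order[::-1]
            return order
    if order[0] > order[-1]:
        return order[::-1]
    return order


def threadmap(
    g: GenotypeMatrix,
    k: int = 3,
    link_threshold: float = 0.2,
    min_informative: int = 20,
    info: Sequence[MarkerInfo] | None = None,
) -> ThreadmapResult:
    """Full projection -> clustering -> per-group ordering pipeline."""
    proj = project(encode_signed(g), k=k)
    pr = pairwise_R(g, min_informative=min_informative)
    groups = cluster_linkage_groups(pr, link_threshold=link_threshold)
    orders = {}
    for lg in dict.fromkeys(groups):
        members = list(groups.index[groups == lg])
        if len(members) >= 2:
            orders[lg] = order_along_curve(members, proj, pr, info=info)
        else:
            orders[lg] = OrderingResult(order=members, off_curve_distance={m: 0.0 for m in members})
    return ThreadmapResult(projection=proj, groups=groups, orders=orders, pairwise=pr)


# ---------------------------------------------------------------------------
# Interactive 3-D export

_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>{title}</title>
<style>
body {{ margin:0; font-family:sans-serif; background:#111; color:#eee; }}
#hud {{ position:fixed; top:8px; left:8px; }}
#hover {{ position:fixed; top:8px; right:8px; color:#ffd; }}
canvas {{ display:block; }}
.sw {{ display:inline-block; width:10px; height:10px; margin-right:4px; }}
</style></head><body>
<div id="hud">{legend}</div><div id="hover"></div>
<canvas id="c"></canvas>
<script>
const DATA = {data};
const PALETTE = {palette};
const cv = document.getElementById('c'), ctx = cv.getContext('2d');
let W, H; function resize() {{ W=cv.width=innerWidth; H=cv.height=innerHeight; draw(); }}
let rx = -0.4, ry = 0.6, zoom = 1.0;
function project(p) {{
  let [x,y,z] = p;
  let c1=Math.cos(ry), s1=Math.sin(ry), c2=Math.cos(rx), s2=Math.sin(rx);
  let x1 = c1*x + s1*z, z1 = -s1*x + c1*z;
  let y1 = c2*y - s2*z1, z2 = s2*y + c2*z1;
  let s = zoom * Math.min(W,H) * 0.35;
  return [W/2 + x1*s, H/2 - y1*s, z2];
}}
let screen = [];
function draw() {{
  ctx.fillStyle = '#111'; ctx.fillRect(0,0,W,H); screen = [];
  for (const tr of DATA) {{
    ctx.fillStyle = PALETTE[tr.label];
    for (let i=0;i<tr.pts.length;i++) {{
      const [sx,sy,sz] = project(tr.pts[i]);
      const r = Math.max(1.2, 2.6 - sz);
      ctx.beginPath(); ctx.arc(sx,sy,r,0,6.2832); ctx.fill();
      screen.push([sx,sy,tr.ids[i],tr.label]);
    }}
  }}
}}
let dragging=false, px=0, py=0;
cv.onmousedown = e => {{ dragging=true; px=e.clientX; py=e.clientY; }};
window.onmouseup = () => dragging=false;
window.onmousemove = e => {{
  if (dragging) {{ ry += (e.clientX-px)*0.01; rx += (e.clientY-py)*0.01;
    px=e.clientX; py=e.clientY; draw(); return; }}
  let best=null, bd=100;
  for (const [sx,sy,id,lab] of screen) {{
    const d=(sx-e.clientX)**2+(sy-e.clientY)**2;
    if (d<bd) {{ bd=d; best=id+' ['+lab+']'; }}
  }}
  document.getElementById('hover').textContent = best || '';
}};
cv.onwheel = e => {{ zoom *= e.deltaY<0 ? 1.1 : 0.9; draw(); e.preventDefault(); }};
window.onresize = resize; resize();
</script></body></html>
"""

_COLOR_CYCLE = [
    "#4e79a7", "#f28e2b", "#e15759", "#76b7b2", "#59a14f", "#edc948",
    "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac", "#86bcb6", "#d37295",
]


def export_3d(
    proj: Projection,
    colors: Mapping[str, str],
    path: str | Path,
    labels_subset: Sequence[str] | None = None,
    title: str = "marker projection",
) -> Path:
    """Write a self-contained interactive 3-D scatter of the projection.

    One trace per color label (typically the chromosome assignment);
    hovering shows the marker id.  The file embeds data and viewer code
    inline and performs no network fetches.  ``labels_subset`` restricts the
    export to chosen groups, e.g. one pair of linkage groups.
    """
    if proj.coords.shape[1] < 3:
        raise ValueError("export_3d needs a projection with k >= 3 components")
    wanted = set(labels_subset) if labels_subset is not None else None
    by_label: dict[str, list[int]] = {}
    for i, m in enumerate(proj.markers):
        lab = str(colors.get(m, "unassigned"))
        if wanted is not None and lab not in wanted:
            continue
        by_label.setdefault(lab, []).append(i)
    if not by_label:
        raise ValueError("no markers left after label filtering")
    span = np.abs(proj.coords[:, :3]).max() or 1.0
    traces, palette, legend = [], {}, []
    for j, (lab, idx) in enumerate(sorted(by_label.items())):
        pts = (proj.coords[idx, :3] / span).round(4).tolist()
        traces.append({"label": lab, "ids": [proj.markers[i] for i in idx], "pts": pts})
        color = _COLOR_CYCLE[j % len(_COLOR_CYCLE)]
        palette[lab] = color
        legend.append(f'<span class="sw" style="background:{color}"></span>{lab}')
    html = _HTML_TEMPLATE.format(
        title=title,
        data=json.dumps(traces),
        palette=json.dumps(palette),
        legend=" ".join(legend),
    )
    out = Path(path)
    out.write_text(html)
    return out
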