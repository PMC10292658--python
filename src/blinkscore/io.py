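"""File-format plumbing: trace CSV, multi-page TIFF video, SWC morphology,
branchlet spine tables, lobule measurement tables and YAML config."""
from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import (
    Branch,
    Branchlet,
    EyelidTrace,
    FrameStack,
    LobuleMeasurement,
    NeuronMorphology,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------- traces

def write_trace_csv(trace: EyelidTrace, path: PathLike) -> None:
    pd.DataFrame({"time_ms": trace.time_ms, "value_px": trace.value_px}).to_csv(
        path, index=False
    )


def read_trace_csv(path: PathLike, frame_rate_hz: Optional[float] = None) -> EyelidTrace:
    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy(dtype=float)
    if frame_rate_hz is None:
        frame_rate_hz = 1000.0 / float(np.mean(np.diff(t))) if len(t) > 1 else 0.0
    return EyelidTrace(
        time_ms=t, value_px=df["value_px"].to_numpy(dtype=float),
        frame_rate_hz=frame_rate_hz,
    )


# ---------------------------------------------------------------- video

def write_tiff_stack(stack: FrameStack, path: PathLike) -> None:
    """Multi-page TIFF; timestamps and ROI go into the image description."""
    desc = yaml.safe_dump(
        {"timestamps_ms": stack.timestamps_ms.tolist(), "roi": list(stack.roi)}
    )
    tifffile.imwrite(path, stack.frames, description=desc)


def read_tiff_stack(
    path: PathLike,
    roi: Optional[tuple[int, int, int, int]] = None,
    timestamps_ms: Optional[np.ndarray] = None,
) -> FrameStack:
    """Read a multi-page TIFF; ROI/timestamps fall back to the embedded
    description written by :func:`write_tiff_stack`."""
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        desc = tf.pages[0].tags.get("ImageDescription")
        embedded = yaml.safe_load(desc.value) if desc is not None else {}
    if frames.ndim == 2:
        frames = frames[None]
    if roi is None:
        if "roi" not in embedded:
            raise ValueError("no ROI given and none embedded in the TIFF")
        roi = tuple(embedded["roi"])
    if timestamps_ms is None:
        timestamps_ms = np.asarray(
            embedded.get("timestamps_ms", np.arange(len(frames), dtype=float))
        )
    return FrameStack(frames=frames, timestamps_ms=timestamps_ms, roi=roi)


def read_video(path: PathLike, **kwargs) -> FrameStack:
    """Read a video file (TIFF directly; AVI and friends via imageio)."""
    p = Path(path)
    if p.suffix.lower() in (".tif", ".tiff"):
        return read_tiff_stack(p, **kwargs)
    import imageio.v3 as iio

    frames = iio.imread(p)
    if frames.ndim == 4:  # RGB -> grayscale
        frames = frames.mean(axis=-1).astype(np.uint8)
    ts = kwargs.pop("timestamps_ms", None)
    if ts is None:
        ts = np.arange(len(frames), dtype=float)
    roi = kwargs.pop("roi", None)
    if roi is None:
        raise ValueError("roi required for non-TIFF video")
    return FrameStack(frames=frames, timestamps_ms=np.asarray(ts), roi=roi)


# ---------------------------------------------------------------- SWC

_SOMA_TYPE = 1
_DENDRITE_TYPE = 3


def write_swc(morph: NeuronMorphology, path: PathLike, radius_um: float = 0.5) -> None:
    """Standard 7-column SWC. The soma becomes a single type-1 node at the
    soma center with its equivalent radius; branch polylines become chains
    of type-3 nodes (planar: z = 0)."""
    soma_r = float(
        np.mean(np.linalg.norm(morph.soma_contour - morph.soma_center, axis=1))
    )
    lines = ["# n type x y z radius parent"]
    lines.append(
        f"1 {_SOMA_TYPE} {morph.soma_center[0]:.4f} {morph.soma_center[1]:.4f} "
        f"0.0 {soma_r:.4f} -1"
    )
    next_id = 2
    branch_tip_node: dict[int, int] = {}
    for bi, branch in enumerate(morph.branches):
        parent_node = 1 if branch.parent is None else branch_tip_node[branch.parent]
        start = 0 if branch.parent is None else 1  # child start = parent tip
        for pi in range(start, len(branch.points)):
            x, y = branch.points[pi]
            lines.append(
                f"{next_id} {_DENDRITE_TYPE} {x:.4f} {y:.4f} 0.0 "
                f"{radius_um:.4f} {parent_node}"
            )
            parent_node = next_id
            next_id += 1
        branch_tip_node[bi] = parent_node
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: PathLike) -> NeuronMorphology:
    """Rebuild a planar morphology from SWC, splitting node chains into
    branch polylines at branch points."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        n, t, x, y, z, r, parent = line.split()
        rows.append((int(n), int(t), float(x), float(y), float(r), int(parent)))
    nodes = {n: (t, np.array([x, y]), r, parent) for n, t, x, y, r, parent in rows}
    soma_ids = [n for n, (t, *_rest) in nodes.items() if t == _SOMA_TYPE]
    if not soma_ids:
        raise ValueError("SWC has no soma node")
    soma_id = soma_ids[0]
    center = nodes[soma_id][1]
    soma_r = nodes[soma_id][2]
    children: dict[int, list[int]] = {}
    for n, (_t, _p, _r, parent) in nodes.items():
        children.setdefault(parent, []).append(n)

    branches: list[Branch] = []
    # walk from each dendrite root; a branch ends at a fork or a tip
    stack = [
        (child, soma_id, None) for child in sorted(children.get(soma_id, []))
    ]
    while stack:
        node, start_node, parent_branch = stack.pop(0)
        pts = [nodes[start_node][1]]
        cur = node
        while True:
            pts.append(nodes[cur][1])
            kids = sorted(children.get(cur, []))
            if len(kids) == 1:
                cur = kids[0]
            else:
                break
        idx = len(branches)
        branches.append(Branch(points=np.asarray(pts), parent=parent_branch))
        for kid in kids:
            stack.append((kid, cur, idx))

    ang = np.linspace(0, 2 * np.pi, 24, endpoint=False)
    contour = center + soma_r * np.column_stack([np.cos(ang), np.sin(ang)])
    return NeuronMorphology(
        soma_contour=contour, soma_center=center, branches=branches
    )


# ---------------------------------------------------------------- tables

def write_branchlet_csv(morph: NeuronMorphology, path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "branchlet_id": b.branchlet_id,
                "length_um": b.length_um,
                "n_spines": b.n_spines,
            }
            for b in morph.branchlets
        ]
    ).to_csv(path, index=False)


def read_branchlet_csv(path: PathLike) -> list[Branchlet]:
    df = pd.read_csv(path)
    return [
        Branchlet(
            branchlet_id=int(r.branchlet_id),
            length_um=float(r.length_um),
            n_spines=int(r.n_spines),
        )
        for r in df.itertuples()
    ]


def read_lobule_csv(path: PathLike) -> list[LobuleMeasurement]:
    df = pd.read_csv(path)
    out = []
    for r in df.itertuples():
        out.append(
            LobuleMeasurement(
                lobule_id=str(r.lobule_id),
                layer=str(r.layer),
                area_um2=float(r.area_um2),
                midline_length_um=float(r.midline_length_um),
                n_cells=int(getattr(r, "n_cells", 0)),
                n_folia=int(getattr(r, "n_folia", 0)),
            )
        )
    return out


def load_config(path: PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}
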