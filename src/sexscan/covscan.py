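"""Sex-specific region calling from windowed read-depth tracks.

The procedure mirrors the classic sexed-cohort coverage scan: per-base
depth is aggregated into fixed 1000 bp windows, normalized as
log2(depth + 1), and the two sex groups are compared window by window. A
male-specific seed window is one where no female sample shows any raw
coverage (max raw female depth <= tau_absent) while the male group clears
a presence floor; nearby seeds are merged into regions.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .models import ValidationError

WINDOW_COLUMNS = ["scaffold", "start", "end", "mean_depth"]


@dataclass
class DepthTrack:
    """One sample's windowed depth along scaffolds."""

    sample_id: str
    sex: str
    windows: pd.DataFrame  # columns: scaffold, start, end, mean_depth

    def __post_init__(self) -> None:
        if self.sex not in {"M", "F"}:
            raise ValidationError(f"sex must be M or F, got {self.sex!r}")
        missing = [c for c in WINDOW_COLUMNS if c not in self.windows.columns]
        if missing:
            raise ValidationError(f"window table missing columns {missing}")
        if (self.windows["mean_depth"] < 0).any():
            raise ValidationError("negative depth in window table")


@dataclass(frozen=True)
class SexSpecificRegion:
    scaffold: str
    start: int
    end: int
    length: int
    n_windows: int
    mean_norm_M: float
    mean_norm_F: float
    specificity: str


def window_depth(
    per_base_depth: Union[str, _io.IOBase, pd.DataFrame],
    window_size: int,
    sample_id: str = "",
    sex: str = "M",
    scaffold_lengths: Optional[Dict[str, int]] = None,
) -> DepthTrack:
    """Aggregate a per-base depth dump into tumbling windows.

    Input is the conventional 3-column TSV (scaffold, 1-based position,
    depth); positions absent from the input count as depth zero. Windows
    are non-overlapping, size ``window_size``; a trailing partial window is
    kept with the mean over its actual span. ``scaffold_lengths`` extends
    scaffolds beyond the last reported position (needed when a file omits
    trailing zero-depth bases).
    """
    if window_size < 1:
        raise ValidationError("window_size must be >= 1")
    if isinstance(per_base_depth, pd.DataFrame):
        df = per_base_depth.copy()
        df.columns = ["scaffold", "pos", "depth"]
    else:
        try:
            df = pd.read_csv(
                per_base_depth,
                sep="\t",
                header=None,
                names=["scaffold", "pos", "depth"],
                dtype={"scaffold": str},
            )
        except (ValueError, pd.errors.ParserError) as exc:
            raise ValidationError(f"malformed depth TSV: {exc}") from None
    for col in ("pos", "depth"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if df[["pos", "depth"]].isna().any().any():
        bad = int(df[["pos", "depth"]].isna().any(axis=1).idxmax()) + 1
        raise ValidationError(f"malformed depth row at line {bad}")
    if (df["depth"] < 0).any():
        bad = int((df["depth"] < 0).idxmax()) + 1
        raise ValidationError(f"negative depth at line {bad}")

    rows = []
    # preserve file order of scaffolds, then emit sorted for a stable grid
    for scaffold, grp in df.groupby("scaffold", sort=True):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        if np.any(np.diff(pos) <= 0):
            k = int(np.argmax(np.diff(pos) <= 0))
            line = int(grp.index[k + 1]) + 1
            raise ValidationError(
                f"positions not strictly increasing on {scaffold} at line {line}"
            )
        if pos[0] < 1:
            raise ValidationError(f"positions must be 1-based on {scaffold}")
        length = int(pos[-1])
        if scaffold_lengths and scaffold in scaffold_lengths:
            length = max(length, int(scaffold_lengths[scaffold]))
        dense = np.zeros(length, dtype=np.float64)
        dense[pos - 1] = grp["depth"].to_numpy(dtype=np.float64)
        n_full = length // window_size
        for w in range(n_full):
            s = w * window_size
            rows.append((scaffold, s, s + window_size, dense[s : s + window_size].mean()))
        if length % window_size:
            s = n_full * window_size
            rows.append((scaffold, s, length, dense[s:].mean()))
    windows = pd.DataFrame(rows, columns=WINDOW_COLUMNS)
    return DepthTrack(sample_id=sample_id, sex=sex, windows=windows)


def normalize_depth(track: DepthTrack) -> DepthTrack:
    """log2(depth + 1) normalization; the +1 keeps zero-depth windows at 0."""
    if (track.windows["mean_depth"] < 0).any():
        raise ValidationError("negative depth cannot be normalized")
    w = track.windows.copy()
    w["mean_depth"] = np.log2(w["mean_depth"].to_numpy() + 1.0)
    return DepthTrack(sample_id=track.sample_id, sex=track.sex, windows=w)


def _grid_key(track: DepthTrack) -> pd.DataFrame:
    return track.windows[["scaffold", "start", "end"]].reset_index(drop=True)


def compare_sexes(
    tracks: Sequence[DepthTrack],
    raw_tracks: Sequence[DepthTrack],
) -> pd.DataFrame:
    """Per-window sex comparison of normalized depth.

    ``tracks`` are normalized, ``raw_tracks`` the matching raw tracks (same
    order); the result carries per-sex means of the normalized values plus
    the per-window maximum raw depth of each sex for the absence criterion.
    """
    if not tracks or len(tracks) != len(raw_tracks):
        raise ValidationError("need matching normalized and raw track lists")
    sexes = {t.sex for t in tracks}
    if sexes != {"M", "F"}:
        raise ValidationError("need at least one sample of each sex")
    grid = _grid_key(tracks[0])
    for t in list(tracks[1:]) + list(raw_tracks):
        g = _grid_key(t)
        if not g.equals(grid):
            if len(g) != len(grid):
                raise ValidationError(
                    f"window grid mismatch for sample {t.sample_id!r}: "
                    f"{len(g)} windows vs {len(grid)}"
                )
            diff = (g != grid).any(axis=1)
            first = int(diff.idxmax())
            raise ValidationError(
                f"window grid mismatch for sample {t.sample_id!r} at window "
                f"{first}: {tuple(g.iloc[first])} vs {tuple(grid.iloc[first])}"
            )
    norm = np.stack([t.windows["mean_depth"].to_numpy() for t in tracks])
    raw = np.stack([t.windows["mean_depth"].to_numpy() for t in raw_tracks])
    is_m = np.array([t.sex == "M" for t in tracks])

    out = grid.copy()
    out["mean_norm_F"] = norm[~is_m].mean(axis=0)
    out["mean_norm_M"] = norm[is_m].mean(axis=0)
    out["n_F"] = int((~is_m).sum())
    out["n_M"] = int(is_m.sum())
    out["max_raw_F"] = raw[~is_m].max(axis=0)
    out["max_raw_M"] = raw[is_m].max(axis=0)
    out.attrs["median_raw_depth"] = float(np.median(raw))
    return out


def default_min_present(comparisons: pd.DataFrame) -> float:
    """Presence floor: log2(0.25 * cohort median raw depth + 1).

    The hemizygous sex carries a single copy (about half the autosomal
    depth); a quarter of the cohort median is a loose floor that rejects
    windows dead in both sexes.
    """
    med = comparisons.attrs.get("median_raw_depth")
    if med is None:
        raise ValidationError("comparison table lacks median_raw_depth")
    return float(np.log2(0.25 * med + 1.0))


def call_sex_specific(
    comparisons: pd.DataFrame,
    tau_absent: float = 0.0,
    min_present: Optional[float] = None,
    max_gap: int = 1,
    min_windows: int = 3,
    mode: str = "male_specific",
) -> List[SexSpecificRegion]:
    """Call regions where one sex has no raw coverage and the other is present.

    A seed window satisfies max_raw(absent sex) <= tau_absent and
    mean_norm(present sex) >= min_present. Seeds separated by at most
    ``max_gap`` non-seed windows on one scaffold merge; merged runs with at
    least ``min_windows`` seed windows are reported, spanning the first
    seed's start to the last seed's end.
    """
    if mode not in {"male_specific", "female_specific"}:
        raise ValidationError(f"unknown mode {mode!r}")
    if min_present is None:
        min_present = default_min_present(comparisons)
    if mode == "male_specific":
        absent_raw, present_norm = "max_raw_F", "mean_norm_M"
    else:
        absent_raw, present_norm = "max_raw_M", "mean_norm_F"

    seeds = (comparisons[absent_raw] <= tau_absent) & (
        comparisons[present_norm] >= min_present
    )
    regions: List[SexSpecificRegion] = []
    for scaffold, grp in comparisons.groupby("scaffold", sort=True):
        idx = np.flatnonzero(seeds.loc[grp.index].to_numpy())
        if idx.size == 0:
            continue
        runs: List[List[int]] = [[int(idx[0])]]
        for k in idx[1:]:
            if int(k) - runs[-1][-1] - 1 <= max_gap:
                runs[-1].append(int(k))
            else:
                runs.append([int(k)])
        for run in runs:
            if len(run) < min_windows:
                continue
            sub = grp.iloc[run]
            start = int(sub["start"].iloc[0])
            end = int(sub["end"].iloc[-1])
            regions.append(
                SexSpecificRegion(
                    scaffold=str(scaffold),
                    start=start,
                    end=end,
                    length=end - start,
                    n_windows=len(run),
                    mean_norm_M=float(sub["mean_norm_M"].mean()),
                    mean_norm_F=float(sub["mean_norm_F"].mean()),
                    specificity=mode,
                )
            )
    return regions


def regions_to_bed(regions: Iterable[SexSpecificRegion]) -> pd.DataFrame:
    """BED-style table (0-based half-open) of called regions."""
    return pd.DataFrame(
        [
            {
                "chrom": r.scaffold,
                "chromStart": r.start,
                "chromEnd": r.end,
                "name": r.specificity,
                "score": r.n_windows,
            }
            for r in regions
        ],
        columns=["chrom", "chromStart", "chromEnd", "name", "score"],
    )


def plot_depth_panel(
    comparisons: pd.DataFrame,
    path: str,
    regions: Optional[Sequence[SexSpecificRegion]] = None,
) -> None:
    """Per-scaffold panel of normalized male/female depth with called regions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scaffolds = list(dict.fromkeys(comparisons["scaffold"]))
    fig, axes = plt.subplots(
        len(scaffolds), 1, figsize=(10, 2.2 * len(scaffolds)), squeeze=False
    )
    for ax, scaffold in zip(axes[:, 0], scaffolds):
        sub = comparisons[comparisons["scaffold"] == scaffold]
        mid = (sub["start"] + sub["end"]) / 2
        ax.plot(mid, sub["mean_norm_M"], drawstyle="steps-mid", label="male", lw=1)
        ax.plot(mid, sub["mean_norm_F"], drawstyle="steps-mid", label="female", lw=1)
        for r in regions or []:
            if r.scaffold == scaffold:
                ax.axvspan(r.start, r.end, alpha=0.2, color="red")
        ax.set_ylabel("log2(depth+1)")
        ax.set_title(scaffold, fontsize=9)
    axes[-1, 0].set_xlabel("position (bp)")
    axes[0, 0].legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def reciprocal_overlap(a: tuple, b: tuple) -> float:
    """Reciprocal overlap fraction of two (scaffold, start, end) intervals."""
    if a[0] != b[0]:
        return 0.0
    ov = max(0, min(a[2], b[2]) - max(a[1], b[1]))
    if ov == 0:
        return 0.0
    return min(ov / (a[2] - a[1]), ov / (b[2] - b[1]))
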