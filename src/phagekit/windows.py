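"""Per-window nucleotide identity tracks across a multiple sequence alignment.

For each query sequence, identity to a chosen reference is computed in
windows of 50 reference bases (IGV-style stacked tracks): windows are
defined on the reference's ungapped coordinates so the track x-axis matches
the genome map, and each window also carries a presence flag separating
small indels (which merely depress identity) from genuinely absent regions
(which flip the flag and are drawn as a thin line).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["WindowIdentityTrack", "window_tracks", "select_reference", "tracks_to_dataframe"]


@dataclass(frozen=True)
class WindowIdentityTrack:
    """Identity/presence track of one query against the reference.

    ``ref_start``/``ref_end`` are 1-based inclusive ungapped reference
    coordinates; windows tile the reference, the last may be short.
    ``identity`` is NaN where the window is not present.
    """

    query_id: str
    reference_id: str
    window_size: int
    ref_start: np.ndarray
    ref_end: np.ndarray
    identity: np.ndarray
    present: np.ndarray

    def global_identity(self) -> float:
        """Length-weighted mean identity over all (present) windows."""
        lengths = self.ref_end - self.ref_start + 1
        mask = self.present
        return float(
            np.sum(self.identity[mask] * lengths[mask]) / np.sum(lengths[mask])
        )


def select_reference(
    msa: Mapping[str, str], groups: Sequence[Sequence[str]] | None = None
) -> dict[int, str]:
    """Pick the longest (ungapped) genome of each group as its reference.

    Ties are broken lexicographically by id. With ``groups=None`` all MSA
    members form one group. Returns ``{group_index: reference_id}``.
    """
    if groups is None:
        groups = [list(msa)]
    out: dict[int, str] = {}
    for k, group in enumerate(groups):
        if not group:
            raise ValueError(f"group {k} is empty")
        missing = [g for g in group if g not in msa]
        if missing:
            raise ValueError(f"group {k}: members absent from MSA: {missing}")
        out[k] = min(group, key=lambda g: (-(len(msa[g]) - msa[g].count("-")), g))
    return out


def window_tracks(
    msa: Mapping[str, str],
    reference_id: str,
    window_size: int = 50,
    presence_threshold: float = 0.5,
    query_gap_mode: str = "mismatch",
) -> tuple[dict[str, WindowIdentityTrack], np.ndarray]:
    """Compute per-query window identity tracks against a reference.

    Windows are consecutive runs of ``window_size`` reference non-gap
    columns (the last window may be short). Per window:

    * identity = columns where query equals reference (both non-gap),
      divided by the reference non-gap columns in the window
      (``query_gap_mode="mismatch"``, default) or by the columns where the
      query is also non-gap (``query_gap_mode="exclude"``);
    * present = fraction of window columns where the query is non-gap is at
      least ``presence_threshold``; identity is NaN where not present.

    Returns the per-query tracks and the consensus: the mean identity over
    all queries per window (NaN-aware — absent queries don't contribute).
    """
    if reference_id not in msa:
        raise ValueError(f"reference {reference_id!r} absent from MSA")
    lengths = {len(s) for s in msa.values()}
    if len(lengths) != 1:
        raise ValueError(f"ragged alignment: lengths {sorted(lengths)}")
    if query_gap_mode not in ("mismatch", "exclude"):
        raise ValueError(f"unknown query_gap_mode {query_gap_mode!r}")

    ref = np.frombuffer(msa[reference_id].encode(), dtype="S1")
    ref_cols = np.nonzero(ref != b"-")[0]  # alignment columns where ref has a base
    n_ref = ref_cols.size
    if n_ref == 0:
        raise ValueError(f"reference {reference_id!r} is all gaps")
    n_windows = -(-n_ref // window_size)
    starts = np.arange(n_windows) * window_size
    ends = np.minimum(starts + window_size, n_ref)
    window_of = np.arange(n_ref) // window_size
    window_len = ends - starts

    ref_bases = ref[ref_cols]
    tracks: dict[str, WindowIdentityTrack] = {}
    identity_stack = []
    for qid, qseq in msa.items():
        if qid == reference_id:
            continue
        q = np.frombuffer(qseq.encode(), dtype="S1")[ref_cols]
        q_nongap = q != b"-"
        match = (q == ref_bases) & q_nongap
        match_per_window = np.bincount(window_of, weights=match, minlength=n_windows)
        nongap_per_window = np.bincount(window_of, weights=q_nongap, minlength=n_windows)
        if query_gap_mode == "mismatch":
            denom = window_len.astype(float)
        else:
            denom = nongap_per_window
        with np.errstate(invalid="ignore", divide="ignore"):
            identity = match_per_window / denom
        present = nongap_per_window / window_len >= presence_threshold
        identity = np.where(present, identity, np.nan)
        identity_stack.append(identity)
        tracks[qid] = WindowIdentityTrack(
            query_id=qid,
            reference_id=reference_id,
            window_size=window_size,
            ref_start=starts + 1,
            ref_end=ends,
            identity=identity,
            present=present,
        )
    if identity_stack:
        stack = np.vstack(identity_stack)
        counts = np.sum(~np.isnan(stack), axis=0)
        sums = np.nansum(stack, axis=0)
        consensus = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    else:
        consensus = np.full(n_windows, np.nan)
    return tracks, consensus


def tracks_to_dataframe(tracks: Mapping[str, WindowIdentityTrack]) -> pd.DataFrame:
    """Long-format table: query, ref_start, ref_end, identity, present."""
    frames = []
    for track in tracks.values():
        frames.append(
            pd.DataFrame(
                {
                    "query": track.query_id,
                    "reference": track.reference_id,
                    "ref_start": track.ref_start,
                    "ref_end": track.ref_end,
                    "identity": track.identity,
                    "present": track.present,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
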