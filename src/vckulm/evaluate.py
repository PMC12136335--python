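"""Ground-truth evaluation of estimated tracks (phantom studies).

Identity is scored on links: each estimated detection is attributed to the
nearest ground-truth bubble in its frame (within a tolerance), and a link —
a pair of consecutive points in an estimated track — counts as correct when
both endpoints attribute to the same true bubble. Precision is correct
links over estimated links, recall is correct links over true links.
"""

from __future__ import annotations

import numpy as np

from .tracking import Track


def _truth_index(true_tracks: list[Track]) -> dict[int, list[tuple[float, float, int]]]:
    idx: dict[int, list[tuple[float, float, int]]] = {}
    for tr in true_tracks:
        for (f, x, y, _) in tr.points:
            idx.setdefault(f, []).append((x, y, tr.track_id))
    return idx


def attribute_points(track: Track, truth: dict, tol: float) -> list[int | None]:
    ids: list[int | None] = []
    for (f, x, y, _) in track.points:
        best, best_d = None, tol
        for (tx, ty, tid) in truth.get(f, []):
            d = float(np.hypot(tx - x, ty - y))
            if d <= best_d:
                best, best_d = tid, d
        ids.append(best)
    return ids


def track_identity_f1(est_tracks: list[Track], true_tracks: list[Track],
                      tol: float = 1.0) -> dict:
    """Link-level identity precision/recall/F1 of estimated tracks.

    ``tol`` is the max distance (px) for attributing an estimated point to a
    true bubble. Returns a dict with precision, recall, f1 and the counts.
    """
    truth = _truth_index(true_tracks)
    est_links = correct = 0
    for tr in est_tracks:
        ids = attribute_points(tr, truth, tol)
        for a, b in zip(ids[:-1], ids[1:]):
            est_links += 1
            if a is not None and a == b:
                correct += 1
    true_links = sum(len(tr.points) - 1 for tr in true_tracks
                     if len(tr.points) >= 2)
    precision = correct / est_links if est_links else 0.0
    recall = correct / true_links if true_links else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else 0.0)
    return {"precision": precision, "recall": recall, "f1": f1,
            "correct_links": correct, "est_links": est_links,
            "true_links": true_links}
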