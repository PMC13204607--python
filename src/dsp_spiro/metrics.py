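"""Event-recovery metrics: detected vs. annotated phase-onset times."""
from __future__ import annotations

import numpy as np


def match_event_times(detected, annotated, tol: float = 0.5) -> int:
    """Greedy one-to-one matching count: each annotated event claims its
    nearest unused detected event within ``tol`` seconds."""
    detected = np.sort(np.asarray(detected, dtype=float))
    annotated = np.sort(np.asarray(annotated, dtype=float))
    used: set[int] = set()
    tp = 0
    for a in annotated:
        cands = [(abs(a - d), i) for i, d in enumerate(detected)
                 if abs(a - d) <= tol and i not in used]
        if cands:
            used.add(min(cands)[1])
            tp += 1
    return tp


def event_recall_precision(detected_insp, detected_exp, annotated_insp,
                           annotated_exp, tol: float = 0.5
                           ) -> tuple[float, float]:
    """Recall and precision over inspiration + expiration onsets jointly."""
    tp = (match_event_times(detected_insp, annotated_insp, tol)
          + match_event_times(detected_exp, annotated_exp, tol))
    n_ann = len(annotated_insp) + len(annotated_exp)
    n_det = len(detected_insp) + len(detected_exp)
    recall = tp / n_ann if n_ann else 1.0
    precision = tp / n_det if n_det else 1.0
    return recall, precision
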