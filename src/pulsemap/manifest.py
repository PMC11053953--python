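"""Dataset bookkeeping on clip manifests.

A manifest is a list of per-recording records tracking which clips survive
the two exclusion stages of a multi-subject recording study: stimulus-level
retention (clips whose eliciting video did not show emotional content in the
analysis window are dropped for *every* subject) and per-clip head-movement
rejection.  The reference study design: 110 subjects x 150 stimuli = 16,500
recordings; per-class retained stimulus counts S:27, N:30, D:26, F:22, A:25
(130 per subject); 112 clips then removed for head movement, leaving 14,188.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import EMOTION_CLASSES

__all__ = ["ClipRecord", "make_mock_manifest", "summarize_manifest",
           "DEFAULT_RETAINED_PER_CLASS"]

DEFAULT_RETAINED_PER_CLASS: dict[str, int] = {"S": 27, "N": 30, "D": 26, "F": 22, "A": 25}


@dataclass(frozen=True)
class ClipRecord:
    subject_id: str
    stimulus_id: int
    label: str
    stimulus_retained: bool
    motion_rejected: bool

    @property
    def retained(self) -> bool:
        return self.stimulus_retained and not self.motion_rejected


def make_mock_manifest(
    n_subjects: int = 110,
    stimuli_per_class: int = 30,
    retained_per_class: dict[str, int] | None = None,
    n_motion_rejected: int = 112,
    seed: int = 0,
) -> list[ClipRecord]:
    """Build a manifest with the study's bookkeeping structure.

    Stimuli are grouped by class (``stimuli_per_class`` each); the first
    ``retained_per_class[label]`` of each class are flagged retained for all
    subjects.  ``n_motion_rejected`` retained clips, drawn uniformly under
    the seed, are flagged as head-movement rejections.
    """
    retained_per_class = retained_per_class or dict(DEFAULT_RETAINED_PER_CLASS)
    bad = set(retained_per_class) - set(EMOTION_CLASSES)
    if bad:
        raise ValueError(f"unknown class labels {sorted(bad)}")
    records: list[ClipRecord] = []
    for si in range(n_subjects):
        subject = f"S{si:03d}"
        stim = 0
        for label in EMOTION_CLASSES:
            keep = retained_per_class.get(label, stimuli_per_class)
            for k in range(stimuli_per_class):
                records.append(
                    ClipRecord(subject, stim, label, stimulus_retained=k < keep,
                               motion_rejected=False)
                )
                stim += 1
    retained_idx = [i for i, r in enumerate(records) if r.stimulus_retained]
    if n_motion_rejected > len(retained_idx):
        raise ValueError("more motion rejections than retained clips")
    rng = np.random.default_rng(seed)
    for i in rng.choice(len(retained_idx), size=n_motion_rejected, replace=False):
        r = records[retained_idx[i]]
        records[retained_idx[i]] = ClipRecord(
            r.subject_id, r.stimulus_id, r.label, r.stimulus_retained, True
        )
    return records


def summarize_manifest(records: list[ClipRecord]) -> dict[str, int]:
    """Counts of recordings at each bookkeeping stage."""
    subjects = {r.subject_id for r in records}
    per_subject_retained = sum(
        1 for r in records if r.stimulus_retained and r.subject_id == next(iter(subjects))
    )
    stimulus_retained = sum(r.stimulus_retained for r in records)
    motion_rejected = sum(r.motion_rejected for r in records)
    return {
        "total_recordings": len(records),
        "n_subjects": len(subjects),
        "retained_stimuli_per_subject": per_subject_retained,
        "retained_before_motion": stimulus_retained,
        "motion_rejected": motion_rejected,
        "final_retained": sum(r.retained for r in records),
    }
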