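"""Classify condensate tracks as active or passive from local MSD exponents.

A synthetic cohort mimics tracked condensates: 30% move ballistically along
a persistent heading (motor-driven), 70% diffuse.  Sliding 12-point windows
give a local MSD exponent alpha for every window; alpha > 1 marks active
motion.  The recovered active fraction is compared with the generator's
ground truth.
"""

import numpy as np

from actophase.motility import classify_active, local_msd_exponents
from actophase.synth import TrackCohortSpec, make_tracks

spec = TrackCohortSpec(n_tracks=200, active_fraction=0.30, seed=42)
tracks, labels = make_tracks(spec)
profiles = [local_msd_exponents(t, window=12) for t in tracks]
cls = classify_active(profiles, threshold=1.0)

truth = float(np.mean(list(labels.values())))
print(f"tracks                  : {len(tracks)} x {spec.track_length} frames")
print(f"true active fraction    : {truth:.2f}")
print(f"track-level recovered   : {cls.track_active_fraction:.2f}")
print(f"window-level fraction   : {cls.window_active_fraction:.2f}")
# The track-level fraction (median alpha per track > 1) recovers the
# generator truth; the window-level fraction runs higher because active
# tracks contribute many superdiffusive windows and diffusive tracks
# occasionally fluctuate above alpha = 1.
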