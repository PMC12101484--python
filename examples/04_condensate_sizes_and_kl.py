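"""Speed-conditioned condensate-size distributions and their KL divergence.

Two synthetic cohorts mimic the imaging experiment: a "mock" cohort whose
condensate areas grow with speed (motor-driven transport feeds growth) and
an actin-depolymerized-like cohort (pure diffusion, small constant areas)
used as the prior.  The Kullback-Leibler divergence of each speed interval's
area histogram from the prior grows with speed — fast condensates are the
ones that differ most from the passive pool.
"""

import numpy as np

from actophase.motility import area_distributions_by_speed, kl_divergence
from actophase.synth import TrackCohortSpec, make_tracks

mock = TrackCohortSpec(n_tracks=200, active_fraction=0.5, area_model="speed",
                       area_base=0.3, area_slope=0.4, seed=1)
passive = TrackCohortSpec(n_tracks=200, active_fraction=0.0,
                          area_model="constant", area_base=0.3, seed=2)

tracks_mock, _ = make_tracks(mock)
tracks_passive, _ = make_tracks(passive)

dist = area_distributions_by_speed(tracks_mock)
prior_areas = np.concatenate([t.areas for t in tracks_passive])
prior, _ = np.histogram(prior_areas, bins=dist["area_edges"])
prior = prior / prior.sum()

print("speed interval (um/s)      KL vs passive prior (nats)")
edges = dist["speed_edges"]
for k, h in enumerate(dist["histograms"]):
    if h is None:
        continue
    d = kl_divergence(h, prior)
    print(f"  [{edges[k]:5.2f}, {edges[k + 1]:5.2f})        {d:.3f}")
# Rising KL with the speed interval reproduces the qualitative experimental
# pattern: high-speed condensates have size distributions far from the
# passive (treated) pool.
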