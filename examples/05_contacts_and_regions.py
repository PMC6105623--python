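"""Surface proximity, cell-cell contacts and compartment assignment.

Builds a synthetic macrophage surface lining the subcapsular band,
measures how often cells come within 20 um of it, detects planted
T-B-style contacts, and assigns tracks to tissue compartments.
"""

import numpy as np

import lymphtrack as lt

# --- proximity to a subcapsular macrophage surface -------------------------
surface = lt.make_surface("subcapsular_band", seed=3)
tracks, _ = lt.make_tracks(lt.TPMScenario(
    model=lt.CRWModel(speed_median=6.0, turn_median=60.0), n_cells=100, seed=5))
times, frac = lt.proximity_fraction(tracks, surface)
print(f"fraction of cells within 20 um of the macrophage surface: "
      f"median {np.median(frac):.2f} over {len(times)} timepoints")

# --- planted contact scenario ----------------------------------------------
subjects, partners, truth = lt.make_contact_scenario(3, duration_frames=4, seed=2)
events = lt.contact_events(subjects, partners)
rate = lt.contact_rate(events, subjects[0].duration)
print(f"contacts detected: {len(events)} (planted: {len(truth)}); "
      f"rate = {rate:.2f} per 5 min")
for ev in events:
    print(f"  {ev.subject_id} ~ {ev.partner_id}: {ev.duration / 60:.1f} min")

# --- compartment assignment -------------------------------------------------
regions = lt.RegionModel({
    "SPF": [lt.Box((150.0, 150.0, 15.0), (300.0, 300.0, 30.0))],
    "FM": [lt.Box((150.0, 150.0, 55.0), (300.0, 300.0, 50.0))],
    "GC": [lt.Sphere((150.0, 150.0, 110.0), 40.0)],
})
assignment = lt.assign_tracks_to_regions(tracks, regions)
counts = {}
for label in assignment.values():
    counts[label] = counts.get(label, 0) + 1
print("tracks per compartment (majority-point rule):", counts)
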