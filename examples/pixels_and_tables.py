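"""Coordinate conversion and table round trips.

Converts tracker pixel coordinates to degrees of visual angle with the
exact per-axis arctangent, writes a simulated study to the tab-separated
samples schema, and reads it back.
"""

import tempfile
from pathlib import Path

from microsaccades import (DisplayGeometry, SimulationConfig, pixels_to_degrees,
                           read_samples_table, simulate_study,
                           write_samples_table)

# a 19" 1024x768 display viewed from 650 mm
geometry = DisplayGeometry(resolution=(1024, 768),
                           physical_size=(376.0, 301.0),
                           viewing_distance=650.0)
for px in (512, 612, 712, 1023):
    x_deg, y_deg = pixels_to_degrees(float(px), 384.0, geometry)
    print(f"pixel ({px:4d}, 384) -> ({x_deg:+.3f}, {y_deg:+.3f}) deg")
# the center pixel maps to (0, 0); ~100 px is ~3.2 deg on this display

dataset, _ = simulate_study(SimulationConfig(n_participants=2,
                                             n_trials_per_session=3,
                                             trial_duration=2.0, seed=1))
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "samples.tsv"
    write_samples_table(dataset.trials, path)
    back = read_samples_table(path, dataset.sampling_rate)
    print(f"wrote and re-read {len(back)} trials of "
          f"{back[0].n_samples} samples each; first trial key: {back[0].key()}")
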