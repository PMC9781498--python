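"""Peak-detected functional connectivity from one resting-state recording.

Simulates a 5-minute 32-channel recording with phase coupling planted on the
C3-C4 pair at 21 Hz, runs the Morlet/PLI stage, and prints the strongest
connectivity indices. The planted pair should top the list.
"""

from fcskill.connectivity import AcquisitionSpec, connectivity_pipeline
from fcskill.synthetic import SyntheticDesign, simulate_recording

design = SyntheticDesign(
    n_sessions=1, coupling=(0.85,), planted=(("C3-C4", 21.0),), seed=7
)
recording = simulate_recording(design, session=0, condition="pre")
table = connectivity_pipeline(
    recording, AcquisitionSpec(), metrics=("pli",), centers_hz=(21.0,)
)

top = table.sort_values("value", ascending=False).head(8)
print(top.to_string(index=False))
print(f"\nC3-C4 rank: {int((table.value > table.set_index('pair').value['C3-C4']).sum()) + 1}"
      f" of {len(table)} pairs")
print("\neach value is the maximum 1-s-epoch phase lag index inside the")
print("2-minute analysis window starting 30 s into the recording; values")
print("near 1 mean consistently lagged phase coupling at that frequency.")
print("note the ceiling: a 120-epoch maximum saturates near 1 even for")
print("uncoupled pairs, so the models use its session-to-session variation,")
print("not its absolute level.")
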