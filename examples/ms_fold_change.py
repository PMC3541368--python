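"""Spike-in-normalized XIC fold change of a signature peptide.

Builds treated/control chromatograms for the target peptide (LLVSASQDGK,
monitored at m/z 509.5-511.5) and for a spiked-in trypsin control peptide,
extracts each apex ("100% abundance" value), and normalizes the target's
treated/control ratio by the spike-in's ratio.
"""

from nucleoshift import msquant, synthdata

AMPLITUDES = {
    ("target", "control"): 1.0e6,
    ("target", "treated"): 2.47e6,  # plants a target ratio of 2.47
    ("spike", "control"): 1.0e6,
    ("spike", "treated"): 0.79e6,  # plants a spike-in ratio of 0.79
}

apex = {}
for i, ((role, condition), amplitude) in enumerate(AMPLITUDES.items()):
    window = (509.5, 511.5) if role == "target" else (421.0, 423.0)
    trace = synthdata.gen_trace(
        synthdata.TraceSpec(
            apex_amplitude=amplitude, mz_window=window, noise_sd=1e4, seed=100 + i
        )
    )
    apex[(role, condition)] = msquant.extract_apex(trace)
    print(f"{role:6s} {condition:8s} apex = {apex[(role, condition)]:.3e}")

result = msquant.fold_change_from_apexes(
    apex[("target", "treated")], apex[("target", "control")],
    apex[("spike", "treated")], apex[("spike", "control")],
)
print(f"target ratio      : {result.target_ratio:.3f}   (treated/control, target peptide)")
print(f"spike-in ratio    : {result.spike_ratio:.3f}   (corrects loading/instrument drift)")
print(f"normalized fold   : {result.reported_fold:.2f}   (planted: 2.47/0.79 = 3.13)")

# the m/z window sanity check: the average-mass [M+2H]2+ of the target
# peptide falls inside the instrument window
mz = msquant.peptide_mz("LLVSASQDGK", 2, mass_mode="average")
print(f"LLVSASQDGK [M+2H]2+ (average) = {mz:.2f}, inside [509.5, 511.5]")
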