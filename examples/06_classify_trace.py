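"""Rule-based dynamotype classification from the trace alone.

Generates three seizures of known class and asks the classifier -- which
sees only the voltage trace, its sampling rate and the event times -- to
recover the onset/offset bifurcation pair from the scaling-law evidence.
"""

from dynamotypes import classify_onset_offset, generate_seizure

for onset, offset in [("SN", "SH"), ("SNIC", "SNIC"), ("SupH", "SupH")]:
    rec = generate_seizure((onset, offset), noise_level="none", seed=1, cutoff=None)
    call = classify_onset_offset(rec)
    ev = call.evidence
    print(f"true {onset}/{offset:5s} -> called {call.onset}/{call.offset}")
    print(f"   evidence: dc={ev['dc_shift']['present']}, "
          f"head-interval ratio {ev['head_isi_ratio']:.2f}, "
          f"first-spike amplitude fraction {ev['first_amp_frac']:.2f}, "
          f"terminal amplitude decay {ev['amp_decay']:.2f}")
    if call.ambiguous_with:
        print(f"   reported ambiguity: {call.ambiguous_with}")
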