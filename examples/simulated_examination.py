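"""A full simulated examination: screening, level descent, transcript.

A stochastic observer with a true threshold of 60 arcsec (guess rate 1/10
for the ten-figure bank, 2% lapses, slope 8 per log unit) takes the test
once, then 500 times, showing both a single session record and how
reliably the protocol recovers the underlying threshold.
"""

from rdstereo.observer import SimulatedObserver, recover_stereoacuity
from rdstereo.protocol import run_quantitative, run_screening, session_transcript

observer = SimulatedObserver(
    threshold_arcsec=60.0, guess_rate=0.1, lapse_rate=0.02, slope=8.0,
    mode="stochastic", seed=5,
)

flag, _ = run_screening(observer)
print(f"screening: {flag}\n")

result = run_quantitative(observer, seed=5)
print(session_transcript(result, subject={"name": "sim-01", "age": 30}))

counts = recover_stereoacuity(observer, n_sessions=500, seed=11)
print("recorded stereoacuity over 500 sessions (true threshold 60 arcsec):")
for level in sorted(counts, key=lambda k: (k is None, k)):
    label = "none (referral)" if level is None else f"{level:g} arcsec"
    print(f"  {label:>16}: {counts[level]:4d}  {'#' * (counts[level] // 10)}")
print(
    "\nThe mode sits at the schedule level bracketing the true threshold;\n"
    "spread to neighbouring levels reflects guessing and lapses, not bias."
)
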