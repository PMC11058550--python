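"""The 3-attempt maximal-pressure calibration with the 7.5% repeat rule.

Each round, the participant produces maximal pressure three times.  If the
largest deviation of the peaks from their mean exceeds 7.5% of the mean,
the whole round is repeated; otherwise the mean becomes Pmax, the
reference every task target is expressed against.
"""

from myotrain import evaluate_max_attempts, run_max_calibration

inconsistent = (9.0, 10.0, 11.0)  # rel. deviation 10% -> repeat
consistent = (10.0, 10.5, 9.8)    # rel. deviation ~4%  -> accept

for peaks in (inconsistent, consistent):
    cal = evaluate_max_attempts(peaks)
    print(f"peaks {peaks}: rel_dev={cal.rel_dev:.3f}, accepted={cal.accepted}")

cal = run_max_calibration([inconsistent, consistent])
print(f"loop: accepted after {cal.rounds_used} rounds, Pmax = {cal.pmax:.2f} kPa")
print("Pmax is the mean of the accepted round's peaks; the first round was")
print("rejected because 1.0/10.0 = 10% exceeds the 7.5% consistency limit.")
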