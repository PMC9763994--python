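"""Stopping boundaries for trial conduct: no mid-trial computation needed.

For fixed thresholds, each futility look reduces to a lookup: given the
control responses observed, how many treatment responses are needed to
continue?  The final look is the efficacy boundary.
"""

from ppdesigns import DesignConfig, Thresholds, build_decision_table
from ppdesigns.decision_tables import decision_table_frame

config = DesignConfig(kind="pooled", thresholds=Thresholds(0.9, 0.1))
rules = build_decision_table(config)

for rule in rules:
    kind = "final efficacy boundary" if rule.final else "futility boundary"
    print(f"\nlook {rule.look}: treatment n={rule.n_trt}, control n={rule.n_ctrl} ({kind})")
    frame = decision_table_frame(rule)
    print(frame.head(8).to_string(index=False))
    if len(frame) > 8:
        print(f"  ... {len(frame) - 8} more control-response rows")

print()
print("Read: at look 1 with 0 control responses, the treatment arm needs the")
print("shown minimum responses out of 10 to continue; -1 means no count")
print("suffices.  The boundary never decreases as control responses grow.")
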