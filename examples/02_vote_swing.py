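"""The net-Republican-gain outcome and county swing classes.

g = (R16 - R08) + (D08 - D16), in percentage points: a county's combined
Republican improvement and Democratic decline between the two elections.
A county can show positive g even when the Republican share fell, provided
the Democratic share fell more.
"""

import pandas as pd

from countyswing import (GeneratorConfig, classify_counties, generate_panel,
                         net_republican_gain, vote_totals_delta)
from countyswing.votes import category_percentage

data = generate_panel(GeneratorConfig(seed=1))
gains = net_republican_gain(data.panel)
labels, counts = classify_counties(data.panel)
n = len(labels)

print(f"median net gain: {gains['net_gain'].median():+.1f} points "
      f"(range {gains['net_gain'].min():+.1f} to {gains['net_gain'].max():+.1f})")
for k in ("republican_gain", "democratic_gain", "both_decline", "both_gain"):
    print(f"  {k:16s} {counts[k]:5d} ({category_percentage(counts[k], n)}%)")

# The published county counts give the same arithmetic:
print("\npublished 2016-vs-2008 tallies: "
      f"{category_percentage(2607, 3112)}% of counties swung Republican, "
      f"{category_percentage(108, 3112)}% Democratic, "
      f"{category_percentage(398, 3112)}% saw both parties decline")

totals = pd.DataFrame({"party": ["dem", "dem", "rep", "rep"],
                       "election": [2008, 2016, 2008, 2016],
                       "votes": [69.5e6, 65.9e6, 60.0e6, 63.0e6]})
print("\nnational vote-total change (millions):")
print(vote_totals_delta(totals).to_string(index=False))
# The Democratic candidate lost 3.6M votes vs 2008 while the Republican
# gained 3.0M -- the national backdrop of the county-level swings above.
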