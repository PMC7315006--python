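"""Attention-time statistics on the packaged per-episode summary table.

Ten animals showed attention to the moving prey over 16 trials and 29
attention episodes; 10 episodes immediately preceded a tentacular
strike. The Mann-Whitney U test (normal approximation with continuity
correction) asks whether episodes that end in a strike attempt last
longer than those that do not.
"""

from cuttlekin import load_table1, summarize_attention
from cuttlekin.stats import attention_mann_whitney

fixture = load_table1()
summary = summarize_attention(fixture)

print(f"{fixture.n_animals} animals, {fixture.n_trials} trials, "
      f"{fixture.n_episodes} attention episodes\n")
for _, row in summary.iterrows():
    print(f"  {row['group']:<10s} n={row['n']:>2d}  "
          f"range {row['min_s']:.1f} - {row['max_s']:.1f} s")

res = attention_mann_whitney(fixture)
print(f"\nMann-Whitney U = {res.statistic:g}  (n = {res.n1} vs {res.n2})")
print(f"two-sided p = {res.p_value:.4f}  [{res.approximation}]")
print("\np > 0.05: attention duration does not predict whether a strike follows.")
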