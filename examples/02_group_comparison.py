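"""Compare one clinical group to the reference with the two-test battery.

Generates a small synthetic cohort (reference + hypertensive group),
removes age/gender effects, and runs the density-equality (BA) and
trend (JT) permutation tests on each proxy.  A proxy is individually
discriminant only when both tests reject at 0.05; the direction says on
which side of the reference the group sits.
"""

from ansmap import CohortConfig, adjust_proxies, compare_groups, generate_cohort

cohort = generate_cohort(
    CohortConfig(group_sizes={"Normal": 250, "Hypertensive": 150}), seed=7)
adjusted = adjust_proxies(cohort).table

results = compare_groups(adjusted, reference="Normal", n_perm=1000, seed=7)

print(f"{'proxy':<10} {'BA p':>7} {'JT p(inc)':>10} {'JT p(dec)':>10} "
      f"{'direction':>9}  discriminant")
for r in results:
    mark = "  <-- joint" if r.discriminant else ""
    print(f"{r.proxy:<10} {r.ba_p:7.3f} {r.jt_p_increasing:10.3f} "
          f"{r.jt_p_decreasing:10.3f} {r.direction:>9}{mark}")

n = sum(r.discriminant for r in results)
print(f"\n{n}/{len(results)} proxies individually discriminant "
      "(both tests significant at 0.05; joint nominal level 0.0025)")
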