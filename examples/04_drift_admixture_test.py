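"""The bootstrap coancestry test: a cluster whose members share more
coancestry with another cluster than with each other signals admixture
from a highly drifted source -- ordinary drift or reverse-direction
admixture cannot produce it."""

from coanpipe import CopyingParams, bootstrap_within_between_test
from coanpipe.simdata import simulate_drift_admixture_scenario

params = CopyingParams()
for which in ("split", "mix-into-beta-from-drifted"):
    panel, _ = simulate_drift_admixture_scenario(which, seed=11)
    res = bootstrap_within_between_test(
        panel, panel.metadata["group"], params,
        subsample_size=13, n_resamples=100, seed=0,
    )
    p = res.p.loc["beta", "alpha"]
    print(f"{which:30s} p(beta, alpha) = {p:.4f} "
          f"{'** flagged' if p < 0.02 else '(not flagged)'}")
print("p = (S+1)/(R+1), S = resamples where beta's within-cluster mean "
      "coancestry >= its cross mean with alpha; equal subsample sizes "
      "remove cluster-size bias")
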