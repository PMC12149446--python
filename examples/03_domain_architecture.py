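"""Inter-domain architecture descriptors (ε, θ, DH) on a two-domain toy.

The generator places two helical domains so the descriptors hit exact
targets; measuring them back demonstrates the descriptor definitions, and
the homodimer-asymmetry report mirrors the compact/extended analysis of
DNA-bound receptor dimers.
"""

from nrgeom import (
    DomainGeometry,
    ToySpec,
    chain_domain_geometry,
    circular_dispersion,
    conformational_similarity,
    homodimer_asymmetry,
    make_two_domain_toy,
)

spec = ToySpec(target_epsilon=45.0, target_theta=110.0, target_dihedral=-75.0)
model, dbd, lbd = make_two_domain_toy(spec)
g = chain_domain_geometry(model.chains[0], dbd, lbd)
print(f"ε  (COM distance)     : {g.epsilon:.3f} Å   (target 45)")
print(f"θ  (hinge angle)      : {g.theta:.3f}°  (target 110)")
print(f"DH (hinge torsion)    : {g.dihedral:.3f}°  (target −75)")

cs = circular_dispersion([103.5, 105.5, 100.7, 97.6])
print(f"hinge-angle dispersion: R={cs.mean_resultant_R:.4f}, σ={cs.circular_std:.4f} rad")
print(f"torsional similarity of DH=−75° vs −95°: {conformational_similarity(-75, -95):.3f}")

# a homodimer with one compact (32 Å) and one extended (46 Å) monomer
monomers = [DomainGeometry(32.0, 100.0, -90.0, "dimer", "A"),
            DomainGeometry(46.0, 104.0, -12.0, "dimer", "B")]
report = homodimer_asymmetry(monomers, predicted_epsilon=42.7)
print(f"asymmetric dimer: {report['asymmetric']} (Δε = {report['max_delta_epsilon']:.1f} Å); "
      f"prediction nearest the {report['nearest_state']['kind']} state "
      f"(chain {report['nearest_state']['chain_id']})")
# A prediction matching only one monomer's ε means the model captured a single
# conformational state of a functionally asymmetric dimer.
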