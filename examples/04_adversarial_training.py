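"""Train the adversarial model on synthetic strong binders and generate.

A short demonstration run (10 iterations on a 200-peptide set); the
discriminator's held-out strong-vs-weak balanced accuracy is tracked per
iteration as a read-out of how much binding chemistry it has absorbed.
"""

import pepgan as pg

train_set = pg.generate_dataset(pg.SyntheticConfig(n_strong=100, n_weak=100, seed=1))
held_out = pg.generate_dataset(pg.SyntheticConfig(n_strong=100, n_weak=100, seed=2))
strong = train_set.subset(label="strong")

cfg = pg.GANConfig.desk_scale(seed=0)
cfg.iterations = 10
cfg.batch_size = 60

state, trace = pg.train(pg.init_gan(cfg), strong, cfg, eval_set=held_out)
df = trace.to_frame()
print(df.round(3).to_string(index=False))

generated = pg.generate(state, 10, seed=3)
print("\ngenerated peptides:", generated.sequences)
print("A discriminator loss below ln 2 = 0.69 means it separates real from")
print("generated peptides; the rising balanced-accuracy column shows it")
print("picking up the anchor chemistry that separates strong from weak.")
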