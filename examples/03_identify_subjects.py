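"""End-to-end identification: fit the filter-bank network, classify test beats.

Trains the two-stage PCA filter bank on the train-split beat images, maps
both splits to block-histogram features, fits a linear one-vs-rest classifier
and reports closed-set identification accuracy.
"""

import eecgnet as e

cohort = e.generate_cohort(n_subjects=8, records_per_subject=6,
                           duration=10.0, fs=500.0,
                           noise=e.NoiseSpec(), seed=3)
tr_im, tr_y, te_im, te_y, _, _ = e.cohort_to_images(cohort, 28, 28)

params = e.PCANetParams()  # k=7x7 patches, 8+8 filters, 7x7 blocks, R=0.5
model = e.fit(list(tr_im), params)
F_train = e.transform(model, list(tr_im))
F_test = e.transform(model, list(te_im))
print(f"feature length {F_train.shape[1]} "
      f"(= 2^{params.L2} bins x {params.L1} channels x "
      f"{F_train.shape[1] // (2**params.L2 * params.L1)} blocks)")

clf = e.train_classifier(F_train, tr_y)
acc = e.accuracy(clf.predict(F_test), te_y)
print(f"test identification accuracy: {acc:.2f}% "
      f"on {len(te_y)} beats from {len(set(te_y))} subjects")
# 100% here means every held-out averaged beat was assigned to the right
# person; chance level would be 1/8 = 12.5%.
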