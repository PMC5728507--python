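"""Build a top-h majority-vote ensemble from the swarm's pbest solutions.

After the search, every particle's personal best configuration is retrained
from scratch with a longer epoch budget on all training data; the h
best-scoring of those classifiers vote on each test sample.  The vote
typically beats the median member because collapsed or weak members are
outvoted.
"""

import numpy as np

import swarmtune as st

dataset = st.make_classification_data(n=600, d=16, n_classes=3, separation=3.0, seed=1)
train, test = st.split_train_val(dataset, 0.8, seed=1)
space = st.SearchSpace(neuron_bounds=(8, 32), hidden_layer_count=2)
protocol = st.EvalProtocol(task="classification", eval_epochs=3, final_epochs=8,
                           batch_size=100, split_seed=1)

tr, te = st.split_train_val(train, protocol.lambda_fraction, protocol.split_seed)
fitness = st.make_fitness(space, tr, te, protocol, seed=1)
result = st.run_pso(fitness, space.box(), st.PSOSettings(population_size=8, max_iterations=10, seed=1))

candidates = st.train_final(result.pbest_positions, space, train, protocol, seed=1)
member_acc = [st.accuracy(test.targets, st.predict(c.model, test.features)[1])
              for c in candidates]
ensemble = st.select_top(candidates, h=4)
vote_acc = st.accuracy(test.targets, st.vote_predict(ensemble, test.features))

print("member test accuracies:", np.round(member_acc, 3).tolist())
print(f"median member accuracy: {np.median(member_acc):.4f}")
print(f"top-4 majority-vote accuracy: {vote_acc:.4f}")
# The ensemble aggregates 4 differently-configured networks; its accuracy is
# at least the median member's on most seeds.
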