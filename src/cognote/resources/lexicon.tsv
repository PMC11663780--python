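memory	expert
agitat-	expert
alter	expert
alzheimer	expert
attention	expert
cognit-	expert
confus-	expert
decline	expert
delirium	expert
dementia	expert
difficult	expert
disorientation	expert
drive	expert
evaluat-	expert
exam	expert
forget-	expert
function	expert
impairment	expert
loss	expert
mental	expert
mild	expert
mmse	expert
moca	expert
montreal	expert
mood	expert
neuro-	expert
orientation	expert
psych-	expert
question	expert
recall	expert
remember	expert
score	expert
sleep	expert
speech	expert
word	expert
worse	expert
cognitive	boosted_trees
dementia	boosted_trees
forgetful	boosted_trees
memory	boosted_trees
bnt	attention_net
ftd	attention_net
hoh	attention_net
lbd	attention_net
mci	attention_net
mmse	attention_net
memory	attention_net
moca	attention_net
abstraction	attention_net
aforementioned	attention_net
age	attention_net
alzheimer	attention_net
alzheimers	attention_net
amnestic	attention_net
amyloid	attention_net
aphasa	attention_net
attention	attention_net
attentional	attention_net
auditory	attention_net
behavioral	attention_net
category	attention_net
challenges	attention_net
clock	attention_net
cog	attention_net
cognition	attention_net
cognitive	attention_net
dementia	attention_net
comprehension	attention_net
correctly	attention_net
cube	attention_net
decline	attention_net
deficit	attention_net
deficits	attention_net
delay	attention_net
delayed	attention_net
developmental	attention_net
died	attention_net
difficulties	attention_net
encoding	attention_net
errors	attention_net
executive	attention_net
expressive	attention_net
falls	attention_net
finding	attention_net
fluency	attention_net
forgetful	attention_net
forgetfulness	attention_net
forgets	attention_net
forgetting	attention_net
frailty	attention_net
functional	attention_net
functioning	attention_net
global	attention_net
hearing	attention_net
immediate	attention_net
impaired	attention_net
impairment	attention_net
insight	attention_net
items	attention_net
language	attention_net
lapses	attention_net
learning	attention_net
linguistic	attention_net
moderately	attention_net
multidomain	attention_net
names	attention_net
naming	attention_net
neurocognitive	attention_net
neurodegenerative	attention_net
perseveration	attention_net
personality	attention_net
phonemic	attention_net
processing	attention_net
recall	attention_net
recalling	attention_net
remember	attention_net
remembering	attention_net
repetition	attention_net
retrieval	attention_net
semantic	attention_net
solving	attention_net
span	attention_net
spatial	attention_net
speech	attention_net
trails	attention_net
visual	attention_net
visuospatial	attention_net
word	attention_net
words	attention_net
years	attention_net
altered mental status	llm
aricept	llm
impaired	llm
mci	llm
moca	llm
anxiety	llm
attention	llm
battery of neuropsychological tests	llm
cognition	llm
cognitive changes	llm
cognitive concerns	llm
cognitive decline	llm
cognitive deficits	llm
cognitive difficulties	llm
cognitive impairment	llm
cognitive issues	llm
cognitive symptoms	llm
cognitive-linguistic therapy	llm
concerns	llm
confused	llm
confusion	llm
current level of cognitive functioning	llm
deficits	llm
delayed recall	llm
delirium	llm
dementia	llm
donepezil	llm
executive function	llm
executive functioning	llm
forgetful	llm
forgetfulness	llm
language	llm
major neurocognitive disorder	llm
memory	llm
memory complaints	llm
memory concerns	llm
memory difficulties	llm
memory impairment	llm
memory issues	llm
memory loss	llm
memory problems	llm
mild cognitive impairment	llm
mild dementia	llm
mild neurocognitive disorder	llm
neurocognitive disorder	llm
neurocognitive status	llm
neurodegenerative process	llm
neuropsych testing	llm
neuropsychological evaluation	llm
neuropsychological testing	llm
neuropsychological tests	llm
poor safety awareness	llm
problem solving	llm
processing speed	llm
short term memory loss	llm
vascular dementia	llm
verbal fluency	llm
weakness	llm
word finding difficulties	llm
working memory	llm
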