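breed,size
affenpinscher,small
beagle,medium
basset hound,medium
bichon frise,small
border collie,medium
boston terrier,small
boxer,large
brittany,medium
bulldog,medium
cairn terrier,small
cavalier king charles spaniel,small
chihuahua,small
chinese crested,small
chow chow,medium
cocker spaniel,medium
collie,large
dachshund,small
doberman pinscher,large
english springer spaniel,medium
french bulldog,small
german shepherd,large
german shorthaired pointer,large
golden retriever,large
great dane,large
great pyrenees,large
havanese,small
jack russell terrier,small
labrador retriever,large
lhasa apso,small
maltese,small
mastiff,large
miniature pinscher,small
miniature poodle,small
miniature schnauzer,small
newfoundland,large
papillon,small
pekingese,small
pit bull terrier,medium
american pit bull terrier,medium
staffordshire bull terrier,medium
american staffordshire terrier,medium
pomeranian,small
poodle,medium
standard poodle,large
toy poodle,small
pug,small
rat terrier,small
rhodesian ridgeback,large
rottweiler,large
saint bernard,large
shar pei,medium
shetland sheepdog,medium
shih tzu,small
siberian husky,large
alaskan malamute,large
weimaraner,large
west highland white terrier,small
whippet,medium
yorkshire terrier,small
australian cattle dog,medium
australian shepherd,medium
belgian malinois,large
bernese mountain dog,large
bloodhound,large
akita,large
catahoula,large
cane corso,large
irish setter,large
anatolian shepherd,large
abyssinian,small
american shorthair,medium
bengal,medium
british shorthair,medium
domestic shorthair,medium
domestic mediumhair,medium
domestic longhair,medium
himalayan,medium
maine coon,large
manx,medium
norwegian forest cat,large
persian,medium
ragdoll,large
russian blue,small
siamese,small
snowshoe,medium
sphynx,small
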